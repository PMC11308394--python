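"""Lagged negative-binomial regression of monthly counts on policy indicators.

The count model is NB2 with a log link:

    log mu_t = country intercept + Seas(t) + sum_k beta_k * indicator_k(t - L_k)

    Seas(t) = d1 sin(2 pi t / 12) + g1 cos(2 pi t / 12)
            + d2 sin(4 pi t / 12) + g2 cos(4 pi t / 12)

    Var(Y_t) = mu_t + alpha * mu_t^2

For each indicator the *optimal lag* L is the shift maximizing the
likelihood-ratio improvement over the nuisance model (seasonality +
country intercepts + overdispersion) on a common observation window; a
greedy forward selection by BIC over the indicators at their optimal
lags builds the final multivariate model.  Ordinal policy indicators
enter as level dummies (never as linear scores) and are jointly tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

try:
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    from .changepoint import BaseEstimator  # type: ignore[attr-defined]

from .io_formats import IndicatorPanel, MonthlySeries

logger = logging.getLogger(__name__)


def seasonal_design(t: Sequence[int]) -> np.ndarray:
    """Annual + semiannual Fourier block.

    Columns, in order: sin(2 pi t/12), cos(2 pi t/12), sin(4 pi t/12),
    cos(4 pi t/12).  ``t`` is an integer month index; any 12-periodic
    origin works since only the phase modulo 12 matters.
    """
    t = np.asarray(t, dtype=float)
    w = 2.0 * np.pi * t / 12.0
    return np.column_stack([np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)])


SEASONAL_NAMES = ("sin_annual", "cos_annual", "sin_semiannual", "cos_semiannual")


@dataclass
class NBFit:
    """Fitted NB2 regression.

    ``params`` holds named log-scale coefficients; ``alpha`` is the NB2
    overdispersion (variance = mu + alpha mu^2).  ``bic`` counts every
    estimated parameter including alpha: BIC = -2 loglik + p log n.
    """

    params: pd.Series
    bse: pd.Series
    alpha: float
    alpha_se: float
    loglik: float
    bic: float
    n: int
    converged: bool
    poisson_boundary: bool = False

    @property
    def n_params(self) -> int:
        return len(self.params) + 1  # + alpha

    def irr_table(self, alpha_level: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha_level / 2)
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "irr": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
                "p": 2 * stats.norm.sf(np.abs(self.params / self.bse.replace(0, np.nan))),
            }
        )

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "alpha": float(self.alpha),
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n": int(self.n),
            "converged": bool(self.converged),
            "poisson_boundary": bool(self.poisson_boundary),
        }


@dataclass
class LagScanResult:
    indicator: str
    lag_grid: list[int]
    loglik_by_lag: dict[int, float]
    p_by_lag: dict[int, float]
    optimal_lag: int
    irr_at_optimum: pd.DataFrame
    nuisance_loglik: float

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "lag_grid": list(map(int, self.lag_grid)),
            "loglik_by_lag": {int(k): float(v) for k, v in self.loglik_by_lag.items()},
            "p_by_lag": {int(k): float(v) for k, v in self.p_by_lag.items()},
            "optimal_lag": int(self.optimal_lag),
            "irr_at_optimum": self.irr_at_optimum.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "nuisance_loglik": float(self.nuisance_loglik),
        }


@dataclass
class NuisanceSpec:
    """Which nuisance terms enter every count model.

    Seasonality and country intercepts (plus NB overdispersion) are the
    default nuisance block; the linear trend, months-since-onset and
    pandemic-period terms are candidate covariates rather than nuisance
    unless switched on here.
    """

    seasonality: bool = True
    country_intercepts: bool = True
    trend: bool = False
    months_since_onset: bool = False
    pandemic_indicator: bool = False
    onset_month: str | pd.Period | None = None

    def to_dict(self) -> dict:
        return {
            "seasonality": self.seasonality,
            "country_intercepts": self.country_intercepts,
            "trend": self.trend,
            "months_since_onset": self.months_since_onset,
            "pandemic_indicator": self.pandemic_indicator,
            "onset_month": None if self.onset_month is None else str(self.onset_month),
        }


class NegativeBinomialGLM(BaseEstimator):
    """NB2 count regression (log link) with jointly estimated overdispersion.

    A thin estimator facade over the maximum-likelihood NB2 fit: both the
    coefficients and alpha are estimated by Newton-type optimization of
    the joint likelihood.  When the data are equidispersed the alpha
    estimate collapses to the Poisson boundary; the fit then falls back
    to a Poisson GLM with ``alpha = 0`` and is flagged.

    Attributes after ``fit``: ``coef_``, ``se_``, ``alpha_``,
    ``loglik_``, ``bic_``, ``converged_``, ``poisson_boundary_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, offset=None, start_params=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        y = y.astype(float)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X, loglike_method="nb2", offset=offset)
            pois0 = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            if start_params is None:
                # Poisson coefficients + moment estimate of alpha make a
                # reliable start; the optimizer's own defaults often stall
                # on designs without a global intercept
                mu0 = np.asarray(pois0.fittedvalues)
                alpha0 = float(np.mean((y - mu0) ** 2 - mu0) / np.mean(mu0**2))
                start_params = np.append(np.asarray(pois0.params), max(alpha0, 0.01))

            def _ok(r):
                return (
                    r is not None
                    and np.all(np.isfinite(r.params))
                    and np.all(np.isfinite(r.bse))
                    and r.mle_retvals.get("converged", True)
                )

            attempts = [
                dict(start_params=start_params, method="newton", maxiter=self.max_iter),
                dict(start_params=start_params, method="bfgs", maxiter=500),
                dict(start_params=start_params, method="nm", maxiter=3000),
            ]
            for kw in attempts:
                try:
                    cand = model.fit(disp=0, **kw)
                except Exception:
                    continue
                if _ok(cand):
                    res = cand
                    break
                if res is None and cand is not None and np.all(np.isfinite(cand.params)):
                    res = cand  # best-effort fallback; may still be replaced

        poisson_boundary = False
        if res is not None:
            alpha = float(res.params[-1])
        if res is None or alpha < 1e-6 or not np.all(np.isfinite(res.bse)) or (
            np.isfinite(res.llf) and res.llf < pois0.llf - 1e-6
        ):
            # boundary / optimizer failure: Poisson fit with alpha pinned at 0
            if res is not None and np.isfinite(res.llf) and res.llf > pois0.llf + 1e-6:
                pass  # genuine NB optimum; keep it
            else:
                poisson_boundary = True
                self.coef_ = np.asarray(pois0.params, dtype=float)
                self.se_ = np.asarray(pois0.bse, dtype=float)
                self.alpha_ = 0.0
                self.alpha_se_ = float("nan")
                self.loglik_ = float(pois0.llf)
                self.converged_ = bool(pois0.converged)
        if not poisson_boundary:
            if res is None:
                raise RuntimeError("negative-binomial fit did not converge")
            self.coef_ = np.asarray(res.params[:-1], dtype=float)
            self.se_ = np.asarray(res.bse[:-1], dtype=float)
            self.alpha_ = max(0.0, float(res.params[-1]))
            self.alpha_se_ = float(res.bse[-1])
            self.loglik_ = float(res.llf)
            self.converged_ = bool(res.mle_retvals.get("converged", True))
            if not self.converged_:
                raise RuntimeError(
                    f"negative-binomial fit did not converge: {res.mle_retvals}"
                )
        self.poisson_boundary_ = poisson_boundary
        n, p = len(y), X.shape[1] + 1  # alpha always counted
        self.bic_ = -2.0 * self.loglik_ + p * np.log(n)
        self.n_ = n
        return self

    def predict(self, X, offset=None):
        eta = np.asarray(X, float) @ self.coef_
        if offset is not None:
            eta = eta + np.asarray(offset, float)
        return np.exp(eta)


def fit_negbin(
    design: pd.DataFrame | np.ndarray,
    counts: Sequence[int],
    offset: Sequence[float] | None = None,
    start_params: np.ndarray | None = None,
) -> NBFit:
    """Joint MLE of an NB2 log-link regression; see :class:`NegativeBinomialGLM`."""
    names = (
        list(design.columns)
        if isinstance(design, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(design).shape[1])]
    )
    est = NegativeBinomialGLM().fit(
        np.asarray(design, float), counts, offset=offset, start_params=start_params
    )
    return NBFit(
        params=pd.Series(est.coef_, index=names),
        bse=pd.Series(est.se_, index=names),
        alpha=est.alpha_,
        alpha_se=est.alpha_se_,
        loglik=est.loglik_,
        bic=est.bic_,
        n=est.n_,
        converged=est.converged_,
        poisson_boundary=est.poisson_boundary_,
    )


def build_stacked_frame(
    series_list: Sequence[MonthlySeries], panels: Sequence[IndicatorPanel]
) -> pd.DataFrame:
    """Long frame: one row per (country, month) with count + indicator columns.

    Country series and panels are matched by name; panels must cover each
    series' months.
    """
    panel_by_country = {p.country: p for p in panels}
    frames = []
    for s in series_list:
        p = panel_by_country.get(s.country)
        if p is None:
            raise ValueError(f"no indicator panel for country {s.country!r}")
        months = s.months
        if not months.isin(p.months).all():
            raise ValueError(f"panel for {s.country!r} does not cover the series months")
        f = p.data.loc[months].copy()
        f.insert(0, "count", s.counts)
        f.insert(0, "t", months.asi8)  # months since epoch; 12-periodic phase is calendar-true
        f.insert(0, "month", months)
        f.insert(0, "country", s.country)
        frames.append(f.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def _nuisance_design(df: pd.DataFrame, nuisance: NuisanceSpec) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    countries = sorted(df["country"].unique())
    if nuisance.country_intercepts:
        for c in countries:
            cols[f"country[{c}]"] = (df["country"] == c).to_numpy(dtype=float)
    else:
        cols["intercept"] = np.ones(len(df))
    if nuisance.seasonality:
        seas = seasonal_design(df["t"].to_numpy())
        for j, nm in enumerate(SEASONAL_NAMES):
            cols[nm] = seas[:, j]
    t0 = df["t"].min()
    if nuisance.trend:
        cols["trend"] = (df["t"].to_numpy() - t0) / 12.0
    if nuisance.months_since_onset or nuisance.pandemic_indicator:
        if nuisance.onset_month is None:
            raise ValueError("onset_month required for onset-based nuisance terms")
        onset = pd.Period(nuisance.onset_month, freq="M").ordinal
        since = np.maximum(0, df["t"].to_numpy() - onset)
        if nuisance.months_since_onset:
            cols["months_since_onset"] = since.astype(float)
        if nuisance.pandemic_indicator:
            cols["pandemic_period"] = (df["t"].to_numpy() >= onset).astype(float)
    return pd.DataFrame(cols, index=df.index)


def _lagged_indicator_columns(
    df: pd.DataFrame, indicator: str, lag: int, kind: str
) -> pd.DataFrame:
    """Indicator shifted by ``lag`` months within each country.

    Ordinal indicators expand to one dummy per nonzero level observed in
    the *unshifted* column (so the dummy basis is lag-invariant).
    Months with undefined lagged values get NaN.
    """
    shifted = df.groupby("country", sort=False)[indicator].shift(lag)
    if kind != "ordinal":
        return pd.DataFrame({f"{indicator}(t-{lag})": shifted.to_numpy(dtype=float)})
    levels = sorted(int(v) for v in df[indicator].unique() if v > 0)
    out = {}
    for lev in levels:
        col = np.where(shifted.isna(), np.nan, (shifted == lev).astype(float))
        out[f"{indicator}(t-{lag})=={lev}"] = col
    return pd.DataFrame(out, index=df.index)


def lag_scan(
    series_list: Sequence[MonthlySeries],
    panels: Sequence[IndicatorPanel],
    indicator: str,
    lag_grid: Sequence[int] = tuple(range(13)),
    nuisance: NuisanceSpec | None = None,
) -> LagScanResult:
    """Scan lags of one indicator in the NB2 model.

    For each lag L the model nuisance + indicator(t-L) is fitted on a
    common window (the first ``max(lag_grid)`` months of each country are
    dropped for *every* lag, so log-likelihoods are comparable).  The
    optimal lag maximizes the likelihood-ratio improvement of the
    indicator block over the nuisance-only fit; ties break toward the
    smaller lag.
    """
    nuisance = nuisance or NuisanceSpec()
    lag_grid = sorted(int(v) for v in lag_grid)
    if min(lag_grid) < 0:
        raise ValueError("lags must be non-negative")
    df = build_stacked_frame(series_list, panels)
    kind = "continuous"
    for p in panels:
        if indicator in p.kinds:
            kind = p.kinds[indicator]
            break
    else:
        raise ValueError(f"indicator {indicator!r} not found in panels")
    max_lag = max(lag_grid)
    # common observation window across lags
    keep = df.groupby("country", sort=False).cumcount() >= max_lag
    if df.loc[keep, indicator].nunique() < 1 or df[indicator].nunique() <= 1:
        raise ValueError(f"indicator {indicator!r} is constant: no identifiable effect")

    base = _nuisance_design(df, nuisance)
    y = df["count"].to_numpy()
    null_fit = fit_negbin(base.loc[keep], y[keep.to_numpy()])
    start = np.concatenate([null_fit.params.to_numpy(), [max(null_fit.alpha, 0.05)]])

    ll_by_lag: dict[int, float] = {}
    p_by_lag: dict[int, float] = {}
    fits: dict[int, NBFit] = {}
    for lag in lag_grid:
        lagged = _lagged_indicator_columns(df, indicator, lag, kind)
        design = pd.concat([base, lagged], axis=1)
        sub = design.loc[keep].dropna()
        ysub = df.loc[sub.index, "count"].to_numpy()
        # drop dummies constant within the window (level never observed there)
        drop = [c for c in lagged.columns if sub[c].nunique() <= 1]
        sub = sub.drop(columns=drop)
        k_ind = len(lagged.columns) - len(drop)
        if k_ind == 0:
            ll_by_lag[lag] = null_fit.loglik
            p_by_lag[lag] = 1.0
            continue
        sp = np.concatenate([start[:-1], np.zeros(k_ind), [start[-1]]])
        try:
            fit = fit_negbin(sub, ysub, start_params=sp)
        except RuntimeError:
            logger.warning("lag %d fit failed for %s; lag excluded", lag, indicator)
            ll_by_lag[lag] = -np.inf
            p_by_lag[lag] = 1.0
            continue
        ll_by_lag[lag] = fit.loglik
        g = max(0.0, 2.0 * (fit.loglik - null_fit.loglik))
        p_by_lag[lag] = float(stats.chi2.sf(g, df=k_ind))
        fits[lag] = fit

    optimal = max(ll_by_lag, key=lambda L: (ll_by_lag[L], -L))
    opt_fit = fits.get(optimal, null_fit)
    irr = opt_fit.irr_table()
    ind_rows = [ix for ix in irr.index if ix.startswith(f"{indicator}(")]
    return LagScanResult(
        indicator=indicator,
        lag_grid=lag_grid,
        loglik_by_lag=ll_by_lag,
        p_by_lag=p_by_lag,
        optimal_lag=int(optimal),
        irr_at_optimum=irr.loc[ind_rows],
        nuisance_loglik=null_fit.loglik,
    )


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"steps": self.steps}


def forward_select_bic(
    series_list: Sequence[MonthlySeries],
    panels: Sequence[IndicatorPanel],
    optimal_lags: Mapping[str, int],
    nuisance: NuisanceSpec | None = None,
) -> tuple[NBFit, SelectionTrace]:
    """Greedy forward selection by BIC over indicators at their optimal lags.

    Starts from the nuisance-only model; at each step adds the lagged
    indicator yielding the lowest BIC, stopping when no addition lowers
    the current BIC.  All fits share one observation window (the first
    ``max`` of the candidate lags dropped per country).
    """
    nuisance = nuisance or NuisanceSpec()
    df = build_stacked_frame(series_list, panels)
    kinds: dict[str, str] = {}
    for p in panels:
        kinds.update(p.kinds)
    max_lag = max(optimal_lags.values(), default=0)
    keep = df.groupby("country", sort=False).cumcount() >= max_lag
    base = _nuisance_design(df, nuisance)
    y = df["count"].to_numpy()

    blocks = {
        ind: _lagged_indicator_columns(df, ind, lag, kinds.get(ind, "continuous"))
        for ind, lag in optimal_lags.items()
    }

    def fit_with(chosen: Sequence[str], warm: NBFit | None = None) -> NBFit:
        design = pd.concat([base] + [blocks[i] for i in chosen], axis=1)
        sub = design.loc[keep].dropna()
        drop = [c for c in sub.columns if c not in base.columns and sub[c].nunique() <= 1]
        sub = sub.drop(columns=drop)
        start = None
        if warm is not None:
            coef = {**dict(warm.params)}
            start = np.array(
                [coef.get(c, 0.0) for c in sub.columns] + [max(warm.alpha, 0.02)]
            )
        return fit_negbin(sub, df.loc[sub.index, "count"].to_numpy(), start_params=start)

    current: list[str] = []
    current_fit = fit_with(current)
    trace = SelectionTrace()
    remaining = list(optimal_lags.keys())
    while remaining:
        candidates = {}
        for ind in remaining:
            try:
                candidates[ind] = fit_with(current + [ind], warm=current_fit)
            except RuntimeError:
                logger.warning("candidate %s failed to fit; skipped this step", ind)
        if not candidates:
            break
        best_ind = min(candidates, key=lambda k: candidates[k].bic)
        trace.steps.append(
            {
                "current": list(current),
                "current_bic": float(current_fit.bic),
                "candidate_bics": {k: float(v.bic) for k, v in candidates.items()},
                "added": best_ind if candidates[best_ind].bic < current_fit.bic else None,
            }
        )
        if candidates[best_ind].bic >= current_fit.bic:
            break
        current.append(best_ind)
        current_fit = candidates[best_ind]
        remaining.remove(best_ind)
    return current_fit, trace
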