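"""Before/after patient-profile contrasts.

The response throughout is membership of the *second* period (the months
at or after a country's detected breakpoint).  Covariates are contrasted
via

* closed-form 2x2 odds ratios with Wald confidence intervals and
  likelihood-ratio p-values,
* an IRLS logistic regression (the 2x2 OR is its MLE for a binary
  covariate),
* the screening rule used to build the multivariate model: every
  covariate with univariate p < 0.20 enters,
* a country-random-intercept (multilevel) logistic model maximizing the
  Laplace- or adaptive-Gauss-Hermite-approximated integrated likelihood.

Missing data are handled by per-model complete cases; no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

try:
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    from .changepoint import BaseEstimator  # type: ignore[attr-defined]

from .io_formats import PatientRecord

logger = logging.getLogger(__name__)

#: covariates handled by the profile analyses, in reporting order
DEFAULT_COVARIATES = ("age", "sex", "previous_er_visit", "family_history", "method")

#: covariate -> (reference level, non-reference level); age is continuous
COVARIATE_LEVELS = {
    "sex": ("male", "female"),
    "method": ("self_poisoning", "other"),
    "family_history": ("no", "yes"),
    "previous_er_visit": ("no", "yes"),
}


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: rows = covariate level (reference, other), columns = period.

    ``a``: reference level, first period;  ``b``: reference, second;
    ``c``: other level, first period;      ``d``: other, second.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class ORResult:
    covariate: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    method: str
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "or": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n_used,
            "method": self.method,
            "flags": list(self.flags),
        }


def _lrt_p_2x2(a: float, b: float, c: float, d: float) -> float:
    """Likelihood-ratio (G-test) p for independence in a 2x2 table."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    return float(stats.chi2.sf(max(g, 0.0), df=1))


def univariate_or(
    table: TwoByTwo,
    covariate: str = "",
    strict: bool = False,
    alpha: float = 0.05,
) -> ORResult:
    """Odds ratio of second-period membership, non-reference vs reference level.

    Equals the binary-covariate logistic MLE ``(a*d)/(b*c)``.  The CI is
    Wald on the log-odds scale; the p-value is the likelihood-ratio test.
    Zero cells get the Haldane-Anscombe +0.5 correction on all cells
    (flagged), or raise under ``strict``.
    """
    a, b, c, d = (float(v) for v in table.cells)
    flags: list[str] = []
    if min(a, b, c, d) == 0:
        if strict:
            zero = ("a", "b", "c", "d")[list(table.cells).index(0)]
            raise ValueError(f"zero cell {zero!r} in strict mode")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("haldane_anscombe")
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = est * np.exp(-z * se), est * np.exp(z * se)
    p = _lrt_p_2x2(*(float(v) for v in table.cells))
    return ORResult(
        covariate=covariate,
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        n_used=int(sum(table.cells)),
        method="closed_form",
        flags=tuple(flags),
    )


class LogisticIRLS(BaseEstimator):
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    Supports grouped binomial responses via ``trials``.  Convergence is
    declared when the largest score component falls below ``tol``;
    quasi-separation (any |coefficient| > 15) is flagged but estimates
    are still returned.

    Attributes after ``fit``: ``coef_``, ``se_``, ``loglik_``,
    ``converged_``, ``separation_``, ``n_iter_``, ``cov_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, fit_intercept: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def fit(self, X, y, trials=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        y = np.asarray(y, dtype=float)
        m = np.ones(len(y)) if trials is None else np.asarray(trials, dtype=float)
        if trials is None and not np.all((y == 0) | (y == 1)):
            raise ValueError("response must be binary (or pass trials for binomial)")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify aliased columns by pivoted QR
            _, r, piv = _pivoted_qr(X)
            aliased = sorted(piv[rank:])
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

        beta = np.zeros(X.shape[1])
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            p = special.expit(eta)
            w = m * p * (1 - p)
            score = X.T @ (y - m * p)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = np.maximum(w, 1e-10)
            info = X.T @ (X * w[:, None])
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
            # dampen huge steps (separation paths)
            nrm = np.max(np.abs(step))
            if nrm > 10.0:
                step *= 10.0 / nrm
            beta = beta + step

        eta = X @ beta
        p = special.expit(eta)
        w = np.maximum(m * p * (1 - p), 1e-10)
        info = X.T @ (X * w[:, None])
        cov = np.linalg.pinv(info)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(
                np.sum(y * eta - m * np.logaddexp(0.0, eta))
                + np.sum(np.where(m > 1, _log_binom(m, y), 0.0))
            )
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.loglik_ = ll
        self.converged_ = converged
        self.separation_ = bool(np.any(np.abs(beta) > 15))
        self.n_iter_ = it
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        p = special.expit(X @ self.coef_)
        return np.column_stack([1 - p, p])


def _log_binom(m, y):
    return special.gammaln(m + 1) - special.gammaln(y + 1) - special.gammaln(m - y + 1)


def _pivoted_qr(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, pivoting=True)
    return q, r, piv


def fit_logistic(
    design: np.ndarray | pd.DataFrame,
    response: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """IRLS logistic fit returning a coefficient table.

    ``design`` must already contain the intercept column.  Returns a
    DataFrame with ``coef`` (log-odds), ``se``, ``z``, ``p`` (Wald) per
    column, with ``loglik``, ``converged`` and ``separation`` in
    ``DataFrame.attrs``.
    """
    names = (
        list(design.columns)
        if isinstance(design, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(design).shape[1])]
    )
    est = LogisticIRLS(tol=tol, max_iter=max_iter).fit(np.asarray(design, float), response)
    z = est.coef_ / est.se_
    out = pd.DataFrame(
        {
            "coef": est.coef_,
            "se": est.se_,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=names,
    )
    out.attrs["loglik"] = est.loglik_
    out.attrs["converged"] = est.converged_
    out.attrs["separation"] = est.separation_
    return out


def _records_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "country": r.country,
                "month": pd.Period(r.episode_date, freq="M"),
                "age": r.age,
                "sex": r.sex,
                "method": r.method,
                "family_history": r.family_history,
                "previous_er_visit": r.previous_er_visit,
            }
        )
    return pd.DataFrame(rows)


def _covariate_column(df: pd.DataFrame, cov: str) -> pd.Series:
    """Numeric covariate column: age as-is, categoricals 0=reference, 1=other."""
    if cov == "age":
        return pd.to_numeric(df["age"], errors="coerce")
    ref, other = COVARIATE_LEVELS[cov]
    s = df[cov]
    out = pd.Series(np.nan, index=df.index, dtype=float)
    out[s == ref] = 0.0
    out[s == other] = 1.0
    return out


def _lrt_p_logistic(X: np.ndarray, y: np.ndarray, test_cols: Sequence[int]) -> float:
    """LRT p-value for dropping ``test_cols`` from the design."""
    full = LogisticIRLS().fit(X, y)
    keep = [j for j in range(X.shape[1]) if j not in set(test_cols)]
    null = LogisticIRLS().fit(X[:, keep], y)
    g = max(0.0, 2.0 * (full.loglik_ - null.loglik_))
    return float(stats.chi2.sf(g, df=len(test_cols)))


def _univariate_one(df: pd.DataFrame, cov: str, y: pd.Series) -> ORResult | None:
    x = _covariate_column(df, cov)
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n == 0 or x[ok].nunique() < 2:
        logger.warning("covariate %s has no usable contrast; excluded", cov)
        return None
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    if cov == "age":
        X = np.column_stack([np.ones(n), xv])
        tab = fit_logistic(X, yv)
        est = float(np.exp(tab["coef"].iloc[1]))
        lo = float(np.exp(tab["coef"].iloc[1] - 1.959963984540054 * tab["se"].iloc[1]))
        hi = float(np.exp(tab["coef"].iloc[1] + 1.959963984540054 * tab["se"].iloc[1]))
        p = _lrt_p_logistic(X, yv, [1])
        return ORResult(cov, est, lo, hi, p, n, "irls")
    a = int(((xv == 0) & (yv == 0)).sum())
    b = int(((xv == 0) & (yv == 1)).sum())
    c = int(((xv == 1) & (yv == 0)).sum())
    d = int(((xv == 1) & (yv == 1)).sum())
    return univariate_or(TwoByTwo(a, b, c, d), covariate=cov)


def country_profile_analysis(
    records: Sequence[PatientRecord],
    breakpoint_month: str | pd.Period,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    screen_p: float = 0.20,
) -> dict:
    """Country-specific univariate screen and multivariate logistic model.

    Response = 1 for episodes dated at or after ``breakpoint_month``.
    Covariates with univariate p < ``screen_p`` enter the multivariate
    model (complete cases across the selected covariates).  Returns a
    dict with ``univariate`` (list of :class:`ORResult`), ``selected``
    (covariate names), and ``multivariate`` (adjusted-OR table or None).
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no records")
    bp = pd.Period(breakpoint_month, freq="M")
    y = (df["month"] >= bp).astype(float)
    if y.nunique() < 2:
        raise ValueError("breakpoint outside the data window")

    uni: list[ORResult] = []
    for cov in covariates:
        res = _univariate_one(df, cov, y)
        if res is not None:
            uni.append(res)
    selected = [r.covariate for r in uni if r.p < screen_p]

    multivariate = None
    if selected:
        cols = {cov: _covariate_column(df, cov) for cov in selected}
        sub = pd.DataFrame(cols)
        ok = sub.notna().all(axis=1) & y.notna()
        X = np.column_stack([np.ones(int(ok.sum()))] + [sub.loc[ok, c] for c in selected])
        names = ["intercept"] + list(selected)
        tab = fit_logistic(pd.DataFrame(X, columns=names), y[ok].to_numpy())
        z = 1.959963984540054
        tab["aor"] = np.exp(tab["coef"])
        tab["ci_low"] = np.exp(tab["coef"] - z * tab["se"])
        tab["ci_high"] = np.exp(tab["coef"] + z * tab["se"])
        # LRT p per selected covariate
        lrt = {}
        Xn = np.asarray(X, float)
        yv = y[ok].to_numpy()
        for j, cov in enumerate(selected, start=1):
            lrt[cov] = _lrt_p_logistic(Xn, yv, [j])
        tab["p_lrt"] = [np.nan] + [lrt[c] for c in selected]
        tab.attrs["n"] = int(ok.sum())
        multivariate = tab
    else:
        logger.info("no covariate reached p < %.2f; multivariate step skipped", screen_p)
    return {"univariate": uni, "selected": selected, "multivariate": multivariate}


# ---------------------------------------------------------------------------
# multilevel (country-random-intercept) logistic regression
# ---------------------------------------------------------------------------


@dataclass
class MultilevelFit:
    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma_u: float
    loglik: float
    approximation: str
    converged: bool

    def or_table(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "ci_low": np.exp(self.beta - z * self.se),
                "ci_high": np.exp(self.beta + z * self.se),
                "p": 2 * stats.norm.sf(np.abs(self.beta / self.se)),
            },
            index=self.fixed_names,
        )


class RandomInterceptLogistic(BaseEstimator):
    """Logistic regression with a single Gaussian random intercept.

    The integrated likelihood is approximated by Laplace's method
    (``n_quad=1``, default) or adaptive Gauss-Hermite quadrature with
    ``n_quad`` nodes, and maximized over the fixed effects and the
    random-intercept SD (on the log scale).  Grouped binomial responses
    are supported via ``trials``.

    ``fix_sigma=0`` collapses the model to the pooled logistic fit.
    """

    def __init__(
        self,
        n_quad: int = 1,
        tol: float = 1e-9,
        max_restarts: int = 3,
        fix_sigma: float | None = None,
    ):
        self.n_quad = n_quad
        self.tol = tol
        self.max_restarts = max_restarts
        self.fix_sigma = fix_sigma

    # -- likelihood machinery -------------------------------------------------

    @staticmethod
    def _group_mode(eta0, y, m, sigma2):
        """Newton solve for the mode of the per-group integrand (scalar u)."""
        u = 0.0
        for _ in range(50):
            p = special.expit(eta0 + u)
            g = np.sum(y - m * p) - u / sigma2
            h = -np.sum(m * p * (1 - p)) - 1.0 / sigma2
            step = g / h
            u -= step
            if abs(step) < 1e-12:
                break
        return u

    def _loglik(self, params, X, y, m, group_idx, nodes, weights, fixed_sigma=None):
        beta = params[: X.shape[1]]
        sigma = fixed_sigma if fixed_sigma is not None else float(np.exp(params[-1]))
        eta = X @ beta
        total = 0.0
        if sigma < 1e-8:
            ll = np.sum(y * eta - m * np.logaddexp(0.0, eta) + _log_binom(m, y))
            return float(ll)
        s2 = sigma * sigma
        for idx in group_idx:
            e0, yg, mg = eta[idx], y[idx], m[idx]
            uhat = self._group_mode(e0, yg, mg, s2)
            p = special.expit(e0 + uhat)
            w_info = np.sum(mg * p * (1 - p)) + 1.0 / s2
            tau = 1.0 / np.sqrt(w_info)
            if len(nodes) == 1:
                lj = (
                    np.sum(yg * (e0 + uhat) - mg * np.logaddexp(0.0, e0 + uhat) + _log_binom(mg, yg))
                    - uhat * uhat / (2 * s2)
                    - 0.5 * np.log(s2 * w_info)
                )
            else:
                # adaptive GH centered at the mode with scale tau
                us = uhat + np.sqrt(2.0) * tau * nodes
                vals = []
                for u_k in us:
                    lp = np.sum(
                        yg * (e0 + u_k) - mg * np.logaddexp(0.0, e0 + u_k) + _log_binom(mg, yg)
                    )
                    vals.append(lp - u_k * u_k / (2 * s2) + nodes_sq_cache(u_k, uhat, tau))
                vals = np.asarray(vals)
                lw = np.log(weights) + vals
                lj = special.logsumexp(lw) + np.log(np.sqrt(2.0) * tau) - 0.5 * np.log(2 * np.pi * s2)
            total += lj
        return float(total)

    def fit(self, X, y, groups, trials=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        m = np.ones(len(y)) if trials is None else np.asarray(trials, dtype=float)
        groups = np.asarray(groups)
        labels = pd.unique(groups)
        if len(labels) < 2 and not (self.fix_sigma == 0):
            raise ValueError("need at least 2 groups for a random intercept")
        group_idx = [np.where(groups == g)[0] for g in labels]
        nodes, weights = np.polynomial.hermite.hermgauss(max(1, self.n_quad))

        pooled = LogisticIRLS().fit(X, y, trials=m)
        beta0 = pooled.coef_.copy()

        if self.fix_sigma is not None:
            sigma = float(self.fix_sigma)

            def nll(b):
                return -self._loglik(b, X, y, m, group_idx, nodes, weights, fixed_sigma=sigma)

            res = optimize.minimize(nll, beta0, method="BFGS", options={"gtol": 1e-8})
            beta = res.x
            ll = -res.fun
            cov = _num_hess_inv(nll, beta)
            self.beta_, self.sigma_u_ = beta, sigma
            self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None))
            self.loglik_ = ll
            self.converged_ = bool(res.success)
            self.approximation_ = "laplace" if self.n_quad == 1 else f"agq({self.n_quad})"
            return self

        def nll(params):
            return -self._loglik(params, X, y, m, group_idx, nodes, weights)

        def _converged(res) -> bool:
            # numeric-gradient BFGS often reports precision loss at the
            # optimum; accept a small score instead of res.success alone
            jac_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3
            return bool(res.success or jac_ok)

        best = None
        for start_s in [np.log(0.5), np.log(0.1), np.log(1.5)][: self.max_restarts]:
            x0 = np.concatenate([beta0, [start_s]])
            res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
            if _converged(res):
                break
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("multilevel logistic fit failed to converge")
        params = best.x
        cov = _num_hess_inv(nll, params)
        self.beta_ = params[:-1]
        self.sigma_u_ = float(np.exp(params[-1]))
        self.se_ = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
        self.loglik_ = -float(best.fun)
        self.converged_ = _converged(best)
        self.approximation_ = "laplace" if self.n_quad == 1 else f"agq({self.n_quad})"
        if not self.converged_:
            logger.warning("multilevel fit did not flag convergence; returning best-so-far")
        return self


def nodes_sq_cache(u_k, uhat, tau):
    """Jacobian exponent correction for adaptive GH: + z_k^2 with u = uhat + sqrt(2) tau z."""
    zk = (u_k - uhat) / (np.sqrt(2.0) * tau)
    return zk * zk


def _num_hess_inv(f, x, eps: float = 1e-5):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps * max(1.0, abs(x[i]))
            ej[j] = eps * max(1.0, abs(x[j]))
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * ei[i] * ej[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def multilevel_logistic(
    records: Sequence[PatientRecord] | pd.DataFrame,
    breakpoints: dict[str, str | pd.Period] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    screen_p: float = 0.20,
    n_quad: int = 1,
) -> dict:
    """Univariate + multivariate multilevel logistic analysis across countries.

    ``records`` may be a line-list (with per-country ``breakpoints``
    mapping months to periods) or a pre-built grouped binomial frame with
    columns ``country``, covariate columns, ``y`` (second-period count)
    and ``n`` (total) — the grouped form is used for desk-scale
    reconstructions from published tables.

    Returns ``{"univariate": [ORResult...], "selected": [...],
    "multivariate": MultilevelFit | None, "fits": {cov: MultilevelFit}}``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        grouped = True
    else:
        if breakpoints is None:
            raise ValueError("breakpoints required for line-list input")
        df = _records_frame(records)
        df["y"] = [
            float(row.month >= pd.Period(breakpoints[row.country], freq="M"))
            for row in df.itertuples()
        ]
        grouped = False

    uni: list[ORResult] = []
    fits: dict[str, MultilevelFit] = {}
    usable: list[str] = []
    for cov in covariates:
        if grouped:
            if cov not in df.columns:
                continue
            x = df[cov].to_numpy(dtype=float)
            y = df["y"].to_numpy(dtype=float)
            m = df["n"].to_numpy(dtype=float)
            g = df["country"].to_numpy()
        else:
            xcol = _covariate_column(df, cov)
            ok = xcol.notna()
            if ok.sum() == 0 or xcol[ok].nunique() < 2:
                logger.warning("covariate %s unusable in multilevel model", cov)
                continue
            x = xcol[ok].to_numpy()
            y = df.loc[ok, "y"].to_numpy()
            m = np.ones(len(x))
            g = df.loc[ok, "country"].to_numpy()
        X = np.column_stack([np.ones(len(x)), x])
        est = RandomInterceptLogistic(n_quad=n_quad).fit(X, y, g, trials=m)
        fit = MultilevelFit(
            fixed_names=["intercept", cov],
            beta=est.beta_,
            se=est.se_,
            sigma_u=est.sigma_u_,
            loglik=est.loglik_,
            approximation=est.approximation_,
            converged=est.converged_,
        )
        fits[cov] = fit
        tab = fit.or_table()
        uni.append(
            ORResult(
                covariate=cov,
                estimate=float(tab.loc[cov, "or"]),
                ci_low=float(tab.loc[cov, "ci_low"]),
                ci_high=float(tab.loc[cov, "ci_high"]),
                p=float(tab.loc[cov, "p"]),
                n_used=int(m.sum()),
                method="multilevel",
            )
        )
        usable.append(cov)

    selected = [r.covariate for r in uni if r.p < screen_p]
    multivariate = None
    if selected and not grouped:
        cols = {cov: _covariate_column(df, cov) for cov in selected}
        sub = pd.DataFrame(cols)
        ok = sub.notna().all(axis=1)
        X = np.column_stack([np.ones(int(ok.sum()))] + [sub.loc[ok, c] for c in selected])
        est = RandomInterceptLogistic(n_quad=n_quad).fit(
            X, df.loc[ok, "y"].to_numpy(), df.loc[ok, "country"].to_numpy()
        )
        multivariate = MultilevelFit(
            fixed_names=["intercept"] + list(selected),
            beta=est.beta_,
            se=est.se_,
            sigma_u=est.sigma_u_,
            loglik=est.loglik_,
            approximation=est.approximation_,
            converged=est.converged_,
        )
    return {"univariate": uni, "selected": selected, "multivariate": multivariate, "fits": fits}
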