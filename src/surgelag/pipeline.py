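"""End-to-end orchestration of the three analysis stages.

Stage 1: changepoint detection on each country's monthly episode series
(PELT, Gaussian mean+variance cost).  Stage 2: before/after profile
contrasts (descriptive table, univariate screen, multivariate logistic,
multilevel logistic across countries).  Stage 3: lag scan per indicator
and BIC forward selection to the final multivariate negative-binomial
model.

All artifacts are plain CSV/JSON written under an output directory,
together with a run manifest carrying the seed, package versions, and a
hash of the analysis-relevant configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .changepoint import ChangepointResult, moving_mean, pelt_meanvar
from .io_formats import (
    IndicatorPanel,
    MonthlySeries,
    PatientRecord,
    aggregate_monthly,
    panel_from_csv,
    read_linelist,
    read_oxcgrt,
    series_from_csv,
)
from .lagged_nb import NuisanceSpec, forward_select_bic, lag_scan
from .profile_models import (
    COVARIATE_LEVELS,
    DEFAULT_COVARIATES,
    country_profile_analysis,
    multilevel_logistic,
)
from .synthetic_data import SimulationTruth, default_scenario, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of scenario / real inputs is set."""

    scenario: SimulationTruth | None = None
    linelist_path: str | None = None
    counts_path: str | None = None
    oxcgrt_path: str | None = None
    countries: list[str] | None = None
    window: tuple[str, str] | None = None
    onset_month: str | None = None
    penalty: str | float = "MBIC"
    minseglen: int = 2
    period_overrides: dict[str, str] = field(default_factory=dict)  # country -> breakpoint month
    covariates: Sequence[str] = DEFAULT_COVARIATES
    lag_grid: Sequence[int] = tuple(range(13))
    # the onset-anchored terms travel with every count model by default,
    # mirroring the additional variables of the published analysis
    nuisance: NuisanceSpec = field(
        default_factory=lambda: NuisanceSpec(
            months_since_onset=True, pandemic_indicator=True
        )
    )
    indicators: Sequence[str] | None = None
    outdir: str = "surgelag_run"
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self):
        synthetic = self.scenario is not None
        real = self.linelist_path is not None or self.counts_path is not None
        if synthetic == real:
            raise ValueError("set exactly one of: synthetic scenario, real input paths")

    def analysis_dict(self) -> dict:
        d: dict = {
            "penalty": str(self.penalty),
            "minseglen": self.minseglen,
            "period_overrides": dict(self.period_overrides),
            "covariates": list(self.covariates),
            "lag_grid": list(map(int, self.lag_grid)),
            "nuisance": self.nuisance.to_dict(),
            "indicators": None if self.indicators is None else list(self.indicators),
            "onset_month": self.onset_month,
            "window": None if self.window is None else list(self.window),
            "countries": self.countries,
            "seed": self.seed,
        }
        if self.scenario is not None:
            sc = dataclasses.asdict(self.scenario)
            sc["effects"] = {
                k: {"lag": v["lag"], "beta": v["beta"]} for k, v in sc["effects"].items()
            }
            d["scenario"] = sc
        else:
            d["linelist_path"] = self.linelist_path
            d["counts_path"] = self.counts_path
            d["oxcgrt_path"] = self.oxcgrt_path
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Period):
        return str(o)
    return str(o)


def write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=_json_default) + "\n")


def descriptive_table(
    records: Sequence[PatientRecord],
    series: MonthlySeries,
    breakpoint_month: str | pd.Period,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Two-period sample description for one country.

    Per period: episode count, monthly mean (SD) of the count series, and
    per-covariate N (%) on complete cases, with comparison p-values
    (chi-square without continuity correction for proportions, Welch t
    for age).
    """
    bp = pd.Period(breakpoint_month, freq="M")
    months = series.months
    second = months >= bp
    rows = []
    c1, c2 = series.counts[~second], series.counts[second]
    if len(c1) == 0 or len(c2) == 0:
        raise ValueError("breakpoint must split the series into two non-empty periods")
    t_p = stats.ttest_ind(c1, c2, equal_var=False).pvalue if min(len(c1), len(c2)) > 1 else np.nan
    rows.append(
        {
            "variable": "episodes",
            "period1": f"{int(c1.sum())}",
            "period2": f"{int(c2.sum())}",
            "p": np.nan,
        }
    )
    rows.append(
        {
            "variable": "monthly_mean_sd",
            "period1": f"{c1.mean():.1f} ({c1.std(ddof=1):.1f})",
            "period2": f"{c2.mean():.1f} ({c2.std(ddof=1):.1f})",
            "p": float(t_p),
        }
    )

    df = pd.DataFrame(
        {
            "month": [pd.Period(r.episode_date, freq="M") for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "method": [r.method for r in records],
            "family_history": [r.family_history for r in records],
            "previous_er_visit": [r.previous_er_visit for r in records],
        }
    )
    period2 = df["month"] >= bp
    for cov in covariates:
        if cov == "age":
            a1 = pd.to_numeric(df.loc[~period2, "age"], errors="coerce").dropna()
            a2 = pd.to_numeric(df.loc[period2, "age"], errors="coerce").dropna()
            p = (
                stats.ttest_ind(a1, a2, equal_var=False).pvalue
                if min(len(a1), len(a2)) > 1
                else np.nan
            )
            rows.append(
                {
                    "variable": "age_mean_sd",
                    "period1": f"{a1.mean():.1f} ({a1.std(ddof=1):.1f})" if len(a1) else "",
                    "period2": f"{a2.mean():.1f} ({a2.std(ddof=1):.1f})" if len(a2) else "",
                    "p": float(p),
                }
            )
            continue
        ref, other = COVARIATE_LEVELS[cov]
        # the reported level follows the published table convention:
        # male for sex, "yes" for history/ER, both levels for method
        shown = {"sex": ref, "family_history": other, "previous_er_visit": other}.get(cov)
        sub = df[df[cov].notna() & df[cov].isin([ref, other])]
        n1 = int((~sub["month"].ge(bp)).sum())
        n2 = int(sub["month"].ge(bp).sum())
        tab = np.array(
            [
                [
                    int(((sub[cov] == lev) & ~sub["month"].ge(bp)).sum()),
                    int(((sub[cov] == lev) & sub["month"].ge(bp)).sum()),
                ]
                for lev in (ref, other)
            ]
        )
        if tab.sum() and tab.sum(axis=1).min() >= 0 and n1 and n2 and (tab.sum(axis=1) > 0).all():
            chi_p = float(stats.chi2_contingency(tab, correction=False)[1]) if (
                (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all()
            ) else np.nan
        else:
            chi_p = np.nan
        levels = (ref, other) if cov == "method" else ((shown,) if shown else (other,))
        for lev in levels:
            k1 = int(((sub[cov] == lev) & ~sub["month"].ge(bp)).sum())
            k2 = int(((sub[cov] == lev) & sub["month"].ge(bp)).sum())
            rows.append(
                {
                    "variable": f"{cov}[{lev}]",
                    "period1": f"{k1}/{n1} ({100.0 * k1 / n1:.1f}%)" if n1 else "",
                    "period2": f"{k2}/{n2} ({100.0 * k2 / n2:.1f}%)" if n2 else "",
                    "p": chi_p,
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(config: PipelineConfig) -> dict:
    if config.scenario is not None:
        return simulate_study(config.scenario, seed=config.seed)
    records: list[PatientRecord] = []
    if config.linelist_path:
        records, _ = read_linelist(config.linelist_path)
    if config.counts_path:
        series = series_from_csv(config.counts_path)
    else:
        if config.window is None or config.countries is None:
            raise ValueError("window and countries required to aggregate a line-list")
        series = [
            aggregate_monthly(records, c, config.window) for c in config.countries
        ]
    panels: list[IndicatorPanel] = []
    if config.oxcgrt_path:
        window = config.window or (
            str(series[0].months[0]),
            str(series[0].months[-1]),
        )
        path = config.oxcgrt_path
        if str(path).endswith(".monthly.csv"):
            panels = panel_from_csv(path)
        else:
            panels = [
                read_oxcgrt(path, s.country, (str(s.months[0]), str(s.months[-1])))
                for s in series
            ]
    return {"records": records, "series": series, "panels": panels}


def _primary_breakpoint(
    result: ChangepointResult, onset: pd.Period | None
) -> pd.Period | None:
    """Earliest changepoint at or after the configured pandemic onset."""
    if result.start is None:
        return None
    months = [result.start + b for b in result.breakpoints[:-1]]
    if not months:
        return None
    if onset is None:
        return months[0]
    after = [m for m in months if m >= onset]
    return after[0] if after else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all three stages; write artifacts under ``config.outdir``.

    Returns a dict with the in-memory results and the artifact paths.
    Any stage failure raises with the stage name; artifacts written so
    far are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "load_inputs"
    artifacts: dict[str, str] = {}
    try:
        data = _load_inputs(config)
        series_list: list[MonthlySeries] = data["series"]
        records: list[PatientRecord] = data["records"]
        panels: list[IndicatorPanel] = data["panels"]
        onset = None
        if config.onset_month:
            onset = pd.Period(config.onset_month, freq="M")
        elif config.scenario is not None:
            onset = config.scenario.start_period + (config.scenario.onset_month - 1)

        stage = "changepoint"
        cp_results: dict[str, ChangepointResult] = {}
        breakpoints: dict[str, pd.Period] = {}
        for s in series_list:
            res = pelt_meanvar(s, penalty=config.penalty, minseglen=config.minseglen)
            cp_results[s.country] = res
            override = config.period_overrides.get(s.country)
            bp = pd.Period(override, freq="M") if override else _primary_breakpoint(res, onset)
            if bp is not None:
                breakpoints[s.country] = bp
        write_json(
            {c: r.to_dict() for c, r in cp_results.items()},
            outdir / "changepoints.json",
        )
        artifacts["changepoints"] = str(outdir / "changepoints.json")
        write_json(
            {c: str(b) for c, b in breakpoints.items()}, outdir / "breakpoints.json"
        )
        artifacts["breakpoints"] = str(outdir / "breakpoints.json")
        if config.make_plots:
            _plot_series(series_list, cp_results, outdir)

        stage = "profiles"
        profile_out: dict[str, dict] = {}
        descriptive: dict[str, pd.DataFrame] = {}
        by_country: dict[str, list[PatientRecord]] = {}
        for r in records:
            by_country.setdefault(r.country, []).append(r)
        for s in series_list:
            recs = by_country.get(s.country, [])
            bp = breakpoints.get(s.country)
            if bp is None or not recs:
                logger.info("skipping profiles for %s (no breakpoint or covariates)", s.country)
                continue
            desc = descriptive_table(recs, s, bp, covariates=config.covariates)
            desc.to_csv(outdir / f"table1_{s.country}.csv", index=False, lineterminator="\n")
            descriptive[s.country] = desc
            profile_out[s.country] = country_profile_analysis(
                recs, bp, covariates=config.covariates
            )
        if profile_out:
            _write_profile_tables(profile_out, outdir)
            artifacts["profiles"] = str(outdir / "table2_univariate.csv")
        ml = None
        ml_records = [r for r in records if r.country in breakpoints]
        if ml_records and len(breakpoints) >= 2:
            ml = multilevel_logistic(
                ml_records,
                breakpoints={c: str(b) for c, b in breakpoints.items()},
                covariates=[c for c in config.covariates],
            )
            _write_multilevel_table(ml, outdir)
            artifacts["multilevel"] = str(outdir / "table3_multilevel.csv")

        stage = "lagged_nb"
        scans = {}
        final = None
        trace = None
        if panels:
            nuis = config.nuisance
            if (
                nuis.months_since_onset or nuis.pandemic_indicator
            ) and nuis.onset_month is None:
                if onset is None:
                    raise ValueError("onset_month required for the configured nuisance")
                nuis = dataclasses.replace(nuis, onset_month=str(onset))
            indicators = config.indicators
            if indicators is None:
                indicators = sorted(
                    {col for p in panels for col in p.data.columns}
                )
            for ind in indicators:
                scans[ind] = lag_scan(
                    series_list, panels, ind, lag_grid=config.lag_grid, nuisance=nuis
                )
            write_json({k: v.to_dict() for k, v in scans.items()}, outdir / "lag_scan.json")
            artifacts["lag_scan"] = str(outdir / "lag_scan.json")
            final, trace = forward_select_bic(
                series_list,
                panels,
                {k: v.optimal_lag for k, v in scans.items()},
                nuisance=nuis,
            )
            write_json(
                {
                    "final_model": final.to_dict(),
                    "irr": final.irr_table().reset_index()
                    .rename(columns={"index": "term"})
                    .to_dict(orient="records"),
                    "selection_trace": trace.to_dict(),
                },
                outdir / "final_model.json",
            )
            artifacts["final_model"] = str(outdir / "final_model.json")

        stage = "manifest"
        manifest = {
            "package": "surgelag",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "stages_seconds": round(time.time() - t_start, 3),
            "countries": [s.country for s in series_list],
        }
        write_json(manifest, outdir / "manifest.json")
        artifacts["manifest"] = str(outdir / "manifest.json")
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    return {
        "changepoints": cp_results,
        "breakpoints": breakpoints,
        "descriptive": descriptive,
        "profiles": profile_out,
        "multilevel": ml,
        "lag_scans": scans,
        "final_model": final,
        "selection_trace": trace,
        "artifacts": artifacts,
    }


def _write_profile_tables(profile_out: dict, outdir: Path) -> None:
    uni_rows, multi_rows = [], []
    for country, res in profile_out.items():
        for orr in res["univariate"]:
            uni_rows.append({"country": country, **orr.to_dict()})
        tab = res["multivariate"]
        if tab is not None:
            for term, row in tab.iterrows():
                if term == "intercept":
                    continue
                multi_rows.append(
                    {
                        "country": country,
                        "covariate": term,
                        "aor": row["aor"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                        "p": row["p_lrt"],
                        "n": tab.attrs.get("n"),
                    }
                )
    pd.DataFrame(uni_rows).to_csv(outdir / "table2_univariate.csv", index=False, lineterminator="\n")
    pd.DataFrame(multi_rows).to_csv(
        outdir / "table2_multivariate.csv", index=False, lineterminator="\n"
    )


def _write_multilevel_table(ml: dict, outdir: Path) -> None:
    rows = [{"model": "univariate", **r.to_dict()} for r in ml["univariate"]]
    if ml["multivariate"] is not None:
        tab = ml["multivariate"].or_table()
        for term, row in tab.iterrows():
            if term == "intercept":
                continue
            rows.append(
                {
                    "model": "multivariate",
                    "covariate": term,
                    "or": row["or"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                    "n": None,
                    "method": "multilevel",
                    "flags": [],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "table3_multilevel.csv", index=False, lineterminator="\n")


def _plot_series(series_list, cp_results, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for s in series_list:
        fig, ax = plt.subplots(figsize=(8, 3))
        x = np.arange(len(s.counts))
        ax.plot(x, s.counts, "k-", lw=0.8, label="monthly episodes")
        ax.plot(x, moving_mean(s.counts, 5), "b-", lw=1.5, label="moving mean (5)")
        for b in cp_results[s.country].breakpoints[:-1]:
            ax.axvline(b - 0.5, color="r", ls="--", lw=1)
        ax.set_title(s.country)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"series_{s.country}.png", dpi=100)
        plt.close(fig)
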