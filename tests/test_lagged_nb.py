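import numpy as np
import pandas as pd
import pytest

from surgelag.io_formats import IndicatorPanel, MonthlySeries
from surgelag.lagged_nb import (
    NuisanceSpec,
    SEASONAL_NAMES,
    build_stacked_frame,
    fit_negbin,
    forward_select_bic,
    lag_scan,
    seasonal_design,
)
from surgelag.synthetic_data import (
    IndicatorEffect,
    SimulationTruth,
    default_scenario,
    simulate_counts,
    simulate_indicators,
    simulate_study,
)


class TestSeasonalDesign:
    def test_phase_anchors(self):
        np.testing.assert_allclose(seasonal_design([0])[0], [0, 1, 0, 1], atol=1e-15)
        np.testing.assert_allclose(seasonal_design([3])[0], [1, 0, 0, -1], atol=1e-12)

    def test_periodic_and_orthogonal_over_full_years(self):
        t = np.arange(48)
        S = seasonal_design(t)
        np.testing.assert_allclose(S[:36], S[12:], atol=1e-12)
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9


class TestFitNegbin:
    def test_constant_counts_collapse_to_poisson_boundary(self):
        fit = fit_negbin(np.ones((4, 1)), [3, 3, 3, 3])
        assert np.exp(fit.params.iloc[0]) == pytest.approx(3.0, rel=1e-8)
        assert fit.alpha == 0.0 and fit.poisson_boundary

    def test_poisson_data_gives_tiny_alpha(self, rng):
        X = np.ones((480, 1))
        y = rng.poisson(12.0, 480)
        fit = fit_negbin(X, y)
        assert fit.alpha < 0.01

    def test_loglik_at_least_poisson(self, rng):
        # alpha is a free parameter, so NB2 can never fit worse
        import statsmodels.api as sm

        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        mu = np.exp(2.0 + 0.3 * X[:, 1])
        y = rng.negative_binomial(5, 5 / (5 + mu))
        nb = fit_negbin(X, y)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert nb.loglik >= pois.llf - 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_negbin(np.ones((3, 1)), [1, -1, 2])

    def test_parameter_recovery_on_generative_model(self):
        # per-coefficient 2-SE coverage over repeated draws
        truth = default_scenario(seed=0)
        nuis = NuisanceSpec()
        inside = None
        n_rep = 20
        for seed in range(n_rep):
            truth = default_scenario(seed=seed)
            data = simulate_study(truth, seed=seed)
            df = build_stacked_frame(data["series"], data["panels"])
            cols = {}
            for c in truth.countries:
                cols[f"country[{c}]"] = (df["country"] == c).to_numpy(float)
            S = seasonal_design(df["t"].to_numpy())
            for j, nm in enumerate(SEASONAL_NAMES):
                cols[nm] = S[:, j]
            ct = df.groupby("country", sort=False)["contact_tracing"].shift(11)
            cols["ct1"] = (ct == 1).astype(float)
            cols["ct2"] = (ct == 2).astype(float)
            deaths = df.groupby("country", sort=False)["log_deaths"].shift(3)
            cols["deaths"] = deaths.fillna(0.0)
            X = pd.DataFrame(cols).fillna(0.0)
            fit = fit_negbin(X, df["count"].to_numpy())
            true_vals = (
                [truth.intercepts[c] for c in truth.countries]
                + list(truth.seasonal)
                + [
                    truth.effects["contact_tracing"].beta[1],
                    truth.effects["contact_tracing"].beta[2],
                    truth.effects["log_deaths"].beta,
                ]
            )
            ok = (
                np.abs(fit.params.to_numpy() - np.array(true_vals))
                <= 2 * fit.bse.to_numpy()
            ).astype(int)
            inside = ok if inside is None else inside + ok
        coverage = inside / n_rep
        assert (coverage >= 0.85).all(), coverage


def _two_indicator_setup(seed, true_lag=3, beta=0.5, n_months=72):
    """Single continuous driver with a planted lag plus an inert clone."""
    countries = [f"c{i}" for i in range(4)]
    rng = np.random.default_rng(seed)
    months = pd.period_range("2015-01", periods=n_months, freq="M")
    panels, series = [], []
    truth = SimulationTruth(
        countries=countries,
        n_months=n_months,
        start="2015-01",
        intercepts={c: np.log(12.0) for c in countries},
        seasonal=(0.0, 0.0, 0.0, 0.0),
        effects={"z": IndicatorEffect(lag=true_lag, beta=beta)},
        alpha=0.05,
        seed=seed,
    )
    for c in countries:
        z = np.clip(rng.normal(0, 1, n_months).cumsum() * 0.1 + 1.5, 0, None)
        data = pd.DataFrame({"z": np.round(z, 4)}, index=months)
        panels.append(IndicatorPanel(country=c, data=data, kinds={"z": "continuous"}))
    for i, p in enumerate(panels):
        series.append(simulate_counts(truth, p, seed=seed * 31 + i))
    return series, panels


class TestLagScan:
    def test_recovers_planted_lag_on_random_walk_driver(self):
        hits = 0
        for seed in range(6):
            series, panels = _two_indicator_setup(seed)
            res = lag_scan(series, panels, "z", lag_grid=range(9))
            hits += res.optimal_lag == 3
        assert hits >= 5

    def test_duplicated_indicator_gives_identical_result(self):
        series, panels = _two_indicator_setup(1)
        twins = []
        for p in panels:
            d = p.data.copy()
            d["z_twin"] = d["z"]
            twins.append(
                IndicatorPanel(
                    country=p.country,
                    data=d,
                    kinds={"z": "continuous", "z_twin": "continuous"},
                )
            )
        a = lag_scan(series, twins, "z", lag_grid=range(7))
        b = lag_scan(series, twins, "z_twin", lag_grid=range(7))
        assert a.optimal_lag == b.optimal_lag
        assert a.loglik_by_lag == pytest.approx(b.loglik_by_lag)

    def test_constant_indicator_rejected(self):
        series, panels = _two_indicator_setup(2)
        flat = [
            IndicatorPanel(
                country=p.country,
                data=p.data.assign(flat=1.0),
                kinds={"z": "continuous", "flat": "continuous"},
            )
            for p in panels
        ]
        with pytest.raises(ValueError, match="constant"):
            lag_scan(series, flat, "flat", lag_grid=range(5))

    def test_null_indicator_p_not_anticonservative_after_selection(self):
        # under independence, the LR p at the scan optimum is still usable
        # as a screen: it should rarely be tiny
        tiny = 0
        n_rep = 12
        for seed in range(n_rep):
            series, panels = _two_indicator_setup(seed + 100, beta=0.0)
            res = lag_scan(series, panels, "z", lag_grid=range(7))
            tiny += res.p_by_lag[res.optimal_lag] < 0.005
        assert tiny <= 2

    def test_ordinal_indicator_expands_to_level_dummies(self):
        truth = default_scenario(seed=0)
        data = simulate_study(truth, seed=0)
        onset = str(truth.start_period + truth.onset_month - 1)
        nuis = NuisanceSpec(
            onset_month=onset, months_since_onset=True, pandemic_indicator=True
        )
        res = lag_scan(data["series"], data["panels"], "contact_tracing", nuisance=nuis)
        assert any("==1" in ix for ix in res.irr_at_optimum.index)
        assert any("==2" in ix for ix in res.irr_at_optimum.index)
        assert (res.irr_at_optimum["irr"] > 0).all()


class TestForwardSelection:
    def test_final_bic_never_worse_than_nuisance_only(self):
        truth = default_scenario(seed=0)
        data = simulate_study(truth, seed=0)
        onset = str(truth.start_period + truth.onset_month - 1)
        nuis = NuisanceSpec(
            onset_month=onset, months_since_onset=True, pandemic_indicator=True
        )
        fit, trace = forward_select_bic(
            data["series"],
            data["panels"],
            {"contact_tracing": 11, "log_deaths": 3, "school_closing": 5},
            nuisance=nuis,
        )
        assert trace.steps
        assert fit.bic <= trace.steps[0]["current_bic"] + 1e-9

    def test_true_driver_selected_before_inert_clone(self):
        first_picks = []
        for seed in range(5):
            series, panels = _two_indicator_setup(seed, beta=0.5)
            rng = np.random.default_rng(seed + 999)
            noisy = []
            for p in panels:
                d = p.data.copy()
                d["decoy"] = np.round(
                    np.clip(rng.normal(0, 1, len(d)).cumsum() * 0.1 + 1.5, 0, None), 4
                )
                noisy.append(
                    IndicatorPanel(
                        country=p.country,
                        data=d,
                        kinds={"z": "continuous", "decoy": "continuous"},
                    )
                )
            fit, trace = forward_select_bic(
                series, noisy, {"z": 3, "decoy": 2}
            )
            added = [s["added"] for s in trace.steps if s["added"]]
            first_picks.append(added[0] if added else None)
        assert first_picks.count("z") >= 4

    def test_all_noise_candidates_usually_stop_empty(self):
        stopped_empty = 0
        n_rep = 8
        for seed in range(n_rep):
            series, panels = _two_indicator_setup(seed + 50, beta=0.0)
            fit, trace = forward_select_bic(series, panels, {"z": 2})
            added = [s["added"] for s in trace.steps if s["added"]]
            stopped_empty += not added
        assert stopped_empty > n_rep / 2

    def test_empty_candidate_set_returns_nuisance_fit(self):
        series, panels = _two_indicator_setup(3)
        fit, trace = forward_select_bic(series, panels, {})
        assert trace.steps == []
        assert "country[c0]" in fit.params.index
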