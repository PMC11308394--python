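import numpy as np
import pandas as pd
import pytest

from surgelag.io_formats import IndicatorPanel, MonthlySeries, aggregate_monthly
from surgelag.lagged_nb import seasonal_design
from surgelag.synthetic_data import (
    CovariateMix,
    IndicatorEffect,
    SimulationTruth,
    default_scenario,
    expected_log_mean,
    simulate_counts,
    simulate_indicators,
    simulate_linelist,
    simulate_study,
)


class TestSimulateIndicators:
    def test_policies_null_before_onset(self):
        truth = default_scenario(seed=2)
        for panel in simulate_indicators(truth, seed=2):
            pre = panel.data.iloc[: truth.onset_month - 1]
            for col, kind in panel.kinds.items():
                assert (pre[col] == 0).all(), col

    def test_same_seed_identical_panels(self):
        truth = default_scenario(seed=4)
        a = simulate_indicators(truth, seed=9)
        b = simulate_indicators(truth, seed=9)
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa.data, pb.data)

    def test_contact_tracing_autocorrelation_peaks_at_zero_lag(self):
        truth = default_scenario(seed=0)
        panel = simulate_indicators(truth, seed=0)[0]
        x = panel.column("contact_tracing")
        x = x - x.mean()

        def xcorr(lag):
            return float(np.sum(x[lag:] * x[: len(x) - lag]))

        assert all(xcorr(0) >= xcorr(L) for L in range(1, 12))

    def test_too_short_window_rejected(self):
        truth = default_scenario(seed=0)
        with pytest.raises(ValueError, match="24"):
            simulate_indicators(truth, months=12, seed=0)


def _flat_panel(truth, step_col=None, step_at=None):
    months = pd.period_range(truth.start_period, periods=truth.n_months, freq="M")
    data = pd.DataFrame({"z": np.zeros(truth.n_months)}, index=months)
    kinds = {"z": "continuous"}
    if step_col:
        x = np.zeros(truth.n_months)
        x[step_at:] = 1.0
        data[step_col] = x
        kinds[step_col] = "ordinal"
    return IndicatorPanel(country=truth.countries[0], data=data, kinds=kinds)


class TestSimulateCounts:
    def test_degenerate_poisson_limit(self):
        truth = SimulationTruth(
            countries=["c"], n_months=480, intercepts={"c": np.log(9.0)},
            seasonal=(0, 0, 0, 0), alpha=0.0, seed=0,
        )
        s = simulate_counts(truth, _flat_panel(truth), seed=0)
        se = np.sqrt(9.0 / 480)
        assert abs(s.counts.mean() - 9.0) < 3 * se

    def test_planted_step_with_lag_three(self):
        truth = SimulationTruth(
            countries=["c"], n_months=120, intercepts={"c": np.log(20.0)},
            seasonal=(0, 0, 0, 0), alpha=0.0,
            effects={"x": IndicatorEffect(lag=3, beta={1: np.log(3.0)})},
            seed=0,
        )
        panel = _flat_panel(truth, step_col="x", step_at=60)
        eta = expected_log_mean(truth, panel)
        # mean shifts exactly 3 months after the indicator step
        assert np.allclose(eta[:63], np.log(20.0))
        assert np.allclose(eta[63:], np.log(60.0))
        s = simulate_counts(truth, panel, seed=1)
        assert s.counts[63:].mean() > 2 * s.counts[:63].mean()

    def test_seasonality_twelve_periodic(self):
        t = np.arange(0, 36)
        seas = seasonal_design(t) @ np.array([0.2, -0.1, 0.05, 0.3])
        np.testing.assert_allclose(seas[:24], seas[12:], atol=1e-12)

    def test_same_seed_reproducible(self):
        truth = default_scenario(seed=6)
        panel = simulate_indicators(truth, seed=6)[2]
        a = simulate_counts(truth, panel, seed=11)
        b = simulate_counts(truth, panel, seed=11)
        assert (a.counts == b.counts).all()

    def test_overdispersion_exceeds_poisson(self):
        truth = SimulationTruth(
            countries=["c"], n_months=2000, intercepts={"c": np.log(30.0)},
            seasonal=(0, 0, 0, 0), alpha=0.3, seed=0,
        )
        truth.n_months = 2000
        s = simulate_counts(truth, _flat_panel(truth), seed=3)
        # var = mu + alpha mu^2 = 30 + 270 = 300 >> 30
        assert s.counts.var() > 100


class TestSimulateLinelist:
    def test_monthly_record_counts_conserved(self):
        truth = default_scenario(seed=8)
        series = MonthlySeries("country_1", "2018-01", np.arange(48) % 7)
        records = simulate_linelist(truth, series, seed=8)
        agg = aggregate_monthly(records, "country_1", ("2018-01", "2021-12"))
        np.testing.assert_array_equal(agg.counts, series.counts)

    def test_post_period_female_proportion(self):
        truth = default_scenario(seed=1)
        truth.post = CovariateMix(female=0.9)
        truth.breakpoints["country_1"] = 2
        series = MonthlySeries("country_1", "2018-01", np.r_[[0], np.full(47, 22)])
        records = simulate_linelist(truth, series, seed=21)
        fem = np.mean([r.sex == "female" for r in records])
        n = len(records)
        assert abs(fem - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_sample_or_approaches_truth(self):
        truth = default_scenario(seed=2)
        truth.pre = CovariateMix(female=0.70)
        truth.post = CovariateMix(female=0.85)
        truth.breakpoints["country_1"] = 25
        series = MonthlySeries("country_1", "2018-01", np.full(48, 150))
        records = simulate_linelist(truth, series, seed=5)
        bp = pd.Period("2020-01", freq="M")
        post = np.array([pd.Period(r.episode_date, freq="M") >= bp for r in records])
        fem = np.array([r.sex == "female" for r in records])
        a = (fem & ~post).sum()
        b = (fem & post).sum()
        c = (~fem & ~post).sum()
        d = (~fem & post).sum()
        log_or_hat = np.log((b / a) / (d / c))
        truth_or = (0.85 / 0.15) / (0.70 / 0.30)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(log_or_hat - np.log(truth_or)) < 4 * se

    def test_ages_within_pediatric_range(self):
        truth = default_scenario(seed=3)
        series = MonthlySeries("country_1", "2018-01", np.full(48, 10))
        ages = [r.age for r in simulate_linelist(truth, series, seed=3)]
        assert min(ages) >= 10 and max(ages) <= 17


class TestSimulateStudy:
    def test_deterministic_given_seed(self):
        truth = default_scenario(seed=5)
        a = simulate_study(truth, seed=5)
        b = simulate_study(truth, seed=5)
        for sa, sb in zip(a["series"], b["series"]):
            assert (sa.counts == sb.counts).all()
        assert a["records"] == b["records"]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            SimulationTruth(countries=["c"], pre=CovariateMix(female=1.4))

    def test_breakpoint_outside_window_rejected(self):
        with pytest.raises(ValueError, match="breakpoint"):
            SimulationTruth(countries=["c"], n_months=48, breakpoints={"c": 60})
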