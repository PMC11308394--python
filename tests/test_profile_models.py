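import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from surgelag.profile_models import (
    LogisticIRLS,
    RandomInterceptLogistic,
    TwoByTwo,
    country_profile_analysis,
    fit_logistic,
    multilevel_logistic,
    univariate_or,
)
from surgelag.synthetic_data import CovariateMix, default_scenario, simulate_linelist
from surgelag.io_formats import MonthlySeries


class TestUnivariateOR:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((143, 75, 58, 94), 3.09),  # SA method, Croatia-scale counts
            ((92, 32, 447, 341), 2.19),  # sex, Spain-scale counts
            ((22, 18, 54, 12), 0.27),  # family history, Portugal-scale counts
            ((62, 15, 139, 155), 4.61),  # sex, Croatia-scale counts
        ],
    )
    def test_published_scale_tables(self, cells, expected):
        res = univariate_or(TwoByTwo(*cells))
        assert round(res.estimate, 2) == expected
        assert res.ci_low < res.estimate < res.ci_high

    def test_balanced_table_is_null(self):
        res = univariate_or(TwoByTwo(10, 10, 10, 10))
        assert res.estimate == 1.0
        assert res.p == pytest.approx(1.0)

    def test_zero_cell_haldane_or_strict_error(self):
        res = univariate_or(TwoByTwo(0, 5, 9, 4))
        assert "haldane_anscombe" in res.flags and np.isfinite(res.estimate)
        with pytest.raises(ValueError, match="zero cell"):
            univariate_or(TwoByTwo(0, 5, 9, 4), strict=True)

    def test_agrees_with_irls_logistic(self):
        # closed form and IRLS are the same MLE for a binary covariate
        for cells in [(62, 15, 139, 155), (7, 9, 12, 4), (30, 40, 25, 35)]:
            a, b, c, d = cells
            x = np.r_[np.zeros(a + b), np.ones(c + d)]
            y = np.r_[np.zeros(a), np.ones(b), np.zeros(c), np.ones(d)]
            tab = fit_logistic(np.column_stack([np.ones(len(x)), x]), y)
            closed = univariate_or(TwoByTwo(*cells)).estimate
            assert np.exp(tab["coef"].iloc[1]) == pytest.approx(closed, rel=1e-6)

    @given(
        st.tuples(*[st.integers(1, 80)] * 4)
    )
    @settings(max_examples=60, deadline=None)
    def test_reference_swap_inverts_or(self, cells):
        a, b, c, d = cells
        direct = univariate_or(TwoByTwo(a, b, c, d)).estimate
        swapped = univariate_or(TwoByTwo(c, d, a, b)).estimate
        assert direct == pytest.approx(1.0 / swapped, rel=1e-12)


class TestFitLogistic:
    def test_binary_covariate_matches_cross_product(self):
        y = np.r_[np.zeros(62), np.ones(15), np.zeros(139), np.ones(155)]
        x = np.r_[np.zeros(77), np.ones(294)]
        tab = fit_logistic(np.column_stack([np.ones(len(y)), x]), y)
        assert np.exp(tab["coef"].iloc[1]) == pytest.approx(4.61, abs=0.005)
        assert tab.attrs["converged"]

    def test_all_zero_response_flags_separation(self):
        tab = fit_logistic(np.ones((20, 1)), np.zeros(20))
        assert tab.attrs["separation"]

    def test_irls_optimum_beats_grid(self, rng):
        x = rng.normal(size=30)
        y = (rng.random(30) < special.expit(0.8 * x - 0.2)).astype(float)
        X = np.column_stack([np.ones(30), x])
        est = LogisticIRLS().fit(X, y)

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        grid = [
            loglik(est.coef_[0] + db0, est.coef_[1] + db1)
            for db0 in np.linspace(-1, 1, 33)
            for db1 in np.linspace(-1, 1, 33)
        ]
        assert est.loglik_ >= max(grid) - 1e-8

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(ValueError, match="aliased"):
            fit_logistic(X, np.r_[np.zeros(5), np.ones(5)])


def _country_linelist(seed, female_pre, female_post, sp_pre=0.7, sp_post=0.7, n_per=400):
    """One country, covariate mix shifting (or not) at a known breakpoint."""
    truth = default_scenario(seed=seed)
    truth.pre = CovariateMix(female=female_pre, self_poisoning=sp_pre)
    truth.post = CovariateMix(female=female_post, self_poisoning=sp_post)
    truth.breakpoints = {"country_1": 25}
    counts = np.full(48, n_per // 24)
    series = MonthlySeries("country_1", "2018-01", counts)
    return simulate_linelist(truth, series, seed=seed), "2020-01"


class TestCountryProfileAnalysis:
    def test_screening_rule_keeps_only_shifted_covariates(self):
        records, bp = _country_linelist(7, female_pre=0.60, female_post=0.88)
        out = country_profile_analysis(records, bp, covariates=["sex", "method"])
        assert "sex" in out["selected"]
        assert "method" not in out["selected"]
        assert "sex" in out["multivariate"].index

    def test_no_covariate_below_screen_p_skips_multivariate(self):
        records, bp = _country_linelist(11, female_pre=0.8, female_post=0.8)
        out = country_profile_analysis(
            records, bp, covariates=["sex", "method"], screen_p=1e-6
        )
        assert out["selected"] == [] and out["multivariate"] is None

    def test_breakpoint_outside_window_rejected(self):
        records, _ = _country_linelist(3, 0.8, 0.8)
        with pytest.raises(ValueError, match="breakpoint"):
            country_profile_analysis(records, "2035-01")


class TestRandomInterceptLogistic:
    def test_sigma_zero_equals_pooled_fit(self, sex_period_grouped):
        df = sex_period_grouped
        X = np.column_stack([np.ones(len(df)), df["sex"]])
        mixed = RandomInterceptLogistic(fix_sigma=0.0).fit(
            X, df["y"].to_numpy(float), df["country"].to_numpy(), trials=df["n"].to_numpy(float)
        )
        pooled = LogisticIRLS().fit(X, df["y"].to_numpy(float), trials=df["n"].to_numpy(float))
        np.testing.assert_allclose(mixed.beta_, pooled.coef_, atol=1e-6)

    def test_matches_reference_mixed_model_fit(self, sex_period_grouped):
        # expected values computed once with lme4::glmer on this table
        # (Laplace: OR 1.915772, sigma 0.2456933, logLik -42.77352)
        df = sex_period_grouped
        X = np.column_stack([np.ones(len(df)), df["sex"]])
        est = RandomInterceptLogistic().fit(
            X, df["y"].to_numpy(float), df["country"].to_numpy(), trials=df["n"].to_numpy(float)
        )
        assert np.exp(est.beta_[1]) == pytest.approx(1.915772, abs=2e-4)
        assert est.sigma_u_ == pytest.approx(0.2456933, abs=2e-3)
        assert est.loglik_ == pytest.approx(-42.77352, abs=1e-3)

    def test_quadrature_refines_laplace(self, sex_period_grouped):
        df = sex_period_grouped
        X = np.column_stack([np.ones(len(df)), df["sex"]])
        args = (X, df["y"].to_numpy(float), df["country"].to_numpy())
        kw = {"trials": df["n"].to_numpy(float)}
        lap = RandomInterceptLogistic(n_quad=1).fit(*args, **kw)
        agq = RandomInterceptLogistic(n_quad=25).fit(*args, **kw)
        # lme4 AGQ25 gives OR 1.915761 on this table
        assert np.exp(agq.beta_[1]) == pytest.approx(1.915761, abs=2e-4)
        assert agq.loglik_ >= lap.loglik_ - 1e-6

    def test_parameter_recovery_five_countries(self):
        rng = np.random.default_rng(42)
        n, k = 2000, 5
        sigma_u, beta1 = 0.5, 0.6
        country = rng.integers(0, k, n)
        u = rng.normal(0, sigma_u, k)
        x = rng.integers(0, 2, n).astype(float)
        eta = -0.5 + beta1 * x + u[country]
        y = (rng.random(n) < special.expit(eta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        est = RandomInterceptLogistic().fit(X, y, country)
        assert abs(est.beta_[1] - beta1) < 2 * est.se_[1]


class TestMultilevelWrapper:
    def test_grouped_input_reproduces_reference_or(self, sex_period_grouped):
        out = multilevel_logistic(sex_period_grouped, covariates=["sex"])
        res = out["univariate"][0]
        assert res.method == "multilevel"
        assert res.estimate == pytest.approx(1.9158, abs=1e-3)
        assert res.ci_low < res.estimate < res.ci_high

    def test_linelist_input_recovers_sex_shift(self):
        truth = default_scenario(seed=5)
        truth.pre = CovariateMix(female=0.70)
        truth.post = CovariateMix(female=0.85)
        records = []
        bps = {}
        for i, c in enumerate(truth.countries[:4]):
            truth.breakpoints[c] = 25
            series = MonthlySeries(c, "2018-01", np.full(48, 12))
            records += simulate_linelist(truth, series, seed=100 + i)
            bps[c] = "2020-01"
        out = multilevel_logistic(records, breakpoints=bps, covariates=["sex", "method"])
        true_or = (0.85 / 0.15) / (0.70 / 0.30)
        sex = [r for r in out["univariate"] if r.covariate == "sex"][0]
        assert sex.ci_low < true_or < sex.ci_high
        assert "sex" in out["selected"]
        assert out["multivariate"] is not None
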