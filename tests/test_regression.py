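"""OLS machinery, the dual-criterion screen, and the power oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from lipidflux import synthetic
from lipidflux.pipeline import run_screens, standardize_study
from lipidflux.quantify import standardize
from lipidflux.regression import (
    interaction_term_p,
    ols_fit,
    partial_corr_power,
    screen_plasma_lipid,
    temperature_code,
)

from conftest import make_table
from oracles import ols_oracle


class TestOLSFit:
    def test_exact_linear_fit_is_degenerate(self):
        x = np.arange(6.0)
        X = np.column_stack([np.ones(6), x])
        fit = ols_fit(2.0 * x, X)
        assert fit.degenerate
        assert fit.params[1] == pytest.approx(2.0)
        assert fit.pvalues[1] == 0.0

    def test_matches_statsmodels_on_random_designs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 13))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n)
            fit = ols_fit(y, X)
            ref = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.params, ref.params, rtol=1e-8)
            np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-8)
            np.testing.assert_allclose(fit.pvalues, ref.pvalues, rtol=1e-6, atol=1e-12)
            assert fit.df_resid == ref.df_resid

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 13))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n)
            fit = ols_fit(y, X)
            beta, se, t, p = ols_oracle(y, X)
            np.testing.assert_allclose(fit.params, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.bse, se, rtol=1e-8)

    def test_rank_deficiency_explicit_error(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            ols_fit(np.random.default_rng(0).normal(size=6), X)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            ols_fit(np.zeros(3), np.ones((3, 3)))

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(2000):
            X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
            pvals.append(ols_fit(rng.normal(size=10), X).pvalues[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTemperatureCode:
    def test_coding(self):
        np.testing.assert_array_equal(
            temperature_code(["cold", "room", "cold"]), [0.0, 1.0, 0.0]
        )
        with pytest.raises(ValueError):
            temperature_code(["cold", "hot"])


def _standardized_pair(y_vals, x_vals):
    plasma, _ = standardize(make_table(y_vals[None, :], ["ACar 18:1"], tissue="plasma"))
    tissue, _ = standardize(make_table(x_vals[None, :], ["FA 16:0"], tissue="liver"))
    return plasma, {"liver": tissue}


class TestScreen:
    def test_dual_criterion_blocks_pure_lipid_signal(self, rng):
        """y orthogonal to temperature with x = y: p_lipid tiny but the
        temperature term is null, so the dual criterion must not flag."""
        y = np.tile([1.0, 2, 4, 8, 16, 32], 2) * np.exp(rng.normal(scale=0.01, size=12))
        plasma, tissues = _standardized_pair(y, y)
        rec = screen_plasma_lipid(plasma, tissues, "ACar 18:1").iloc[0]
        assert rec["p_lipid"] < 1e-6
        assert rec["p_temperature"] > 0.5
        assert not rec["significant"]

    def test_significant_iff_both_terms(self, small_study):
        records = run_screens(small_study)
        both = (records["p_temperature"] < 0.05) & (records["p_lipid"] < 0.05)
        assert (records["significant"] == both).all()
        assert records["significant"].sum() <= min(
            (records["p_temperature"] < 0.05).sum(), (records["p_lipid"] < 0.05).sum()
        )

    def test_sign_matches_beta2(self, small_study):
        records = run_screens(small_study)
        assert (
            (records["predictor_sign"] == "positive") == (records["beta2"] >= 0)
        ).all()

    def test_intercept_identity_with_standardized_data(self, small_study):
        """With y and x standardized, beta0 = -beta1 * mean(temperature)."""
        records = run_screens(small_study)
        full_n = records["n"] == 12  # identity is exact only without dropped mice
        sub = records[full_n]
        np.testing.assert_allclose(sub["beta0"], -sub["beta1"] * 0.5, atol=1e-10)

    def test_beta2_reduces_to_simple_slope_when_x_balanced(self):
        """If x is empirically uncorrelated with temperature, the adjusted
        slope equals the unadjusted regression slope of y on x."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        x = x - x.mean()
        t = temperature_code(["cold"] * 6 + ["room"] * 6)
        x -= (x @ (t - t.mean())) / ((t - t.mean()) @ (t - t.mean())) * (t - t.mean())
        y = 0.7 * x + rng.normal(scale=0.5, size=12)
        fit = ols_fit(y, np.column_stack([np.ones(12), t, x]))
        simple = ols_fit(y, np.column_stack([np.ones(12), x]))
        assert fit.params[2] == pytest.approx(simple.params[1], abs=1e-10)

    def test_planted_contributors_flagged_positive(self):
        """Strong-effect regime: every planted link flagged with the
        planted sign."""
        design = synthetic.small_design(seed=17, link_beta2=0.95, noise_sd=0.2)
        study = synthetic.generate_study(design)
        records = run_screens(study)
        metrics = synthetic.evaluate_recovery(records, study.truth)
        assert metrics.sensitivity == 1.0
        assert metrics.sign_accuracy == 1.0
        assert metrics.contributor_top_ranked

    def test_unstandardized_table_rejected(self, small_study):
        tables = small_study.normalized_all()
        plasma = tables.pop("plasma")
        with pytest.raises(ValueError, match="standardized"):
            screen_plasma_lipid(plasma, tables, "ACar 18:1")


class TestInteraction:
    def test_pure_interaction_degenerate(self):
        t = np.array([0.0] * 6 + [1.0] * 6)
        x = np.array([1.0, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6])
        y = t * x
        p, degenerate = interaction_term_p(y, t, x)
        assert degenerate
        assert p == 0.0

    def test_no_interaction_null_uniform(self, rng):
        pvals = []
        t = np.array([0.0] * 6 + [1.0] * 6)
        for _ in range(1000):
            x = rng.normal(size=12)
            y = 0.5 * t + 0.5 * x + rng.normal(size=12)
            pvals.append(interaction_term_p(y, t, x)[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_full_model_oracle(self, rng):
        t = np.array([0.0] * 6 + [1.0] * 6)
        for _ in range(100):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            p, _ = interaction_term_p(y, t, x)
            X = np.column_stack([np.ones(12), t, x, t * x])
            assert p == pytest.approx(ols_oracle(y, X)[3][3], rel=1e-8)


class TestPowerOracle:
    def test_density_normalizes(self):
        from scipy import integrate

        from lipidflux.regression import _sample_corr_pdf

        for rho in (0.0, 0.5, 0.8):
            total, _ = integrate.quad(_sample_corr_pdf, -1, 1, args=(rho, 11), limit=200)
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_null_power_is_alpha(self):
        assert partial_corr_power(1e-12, 12) == pytest.approx(0.05, abs=1e-3)

    def test_matches_monte_carlo(self, rng):
        n, reps, rho = 12, 4000, 0.8
        t = np.array([0.0] * 6 + [1.0] * 6)
        hits = 0
        for _ in range(reps):
            f = rng.normal(size=n)
            x = 0.5 * t + np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
            y = 1.0 * t + np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
            fit = ols_fit(y, np.column_stack([np.ones(n), t, x]))
            hits += fit.pvalues[2] < 0.05
        mc = hits / reps
        se = np.sqrt(mc * (1 - mc) / reps)
        assert partial_corr_power(rho, n) == pytest.approx(mc, abs=4 * se + 0.005)
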