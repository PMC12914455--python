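"""FIML regression, robustness estimators, MCAR diagnostics, sensitivity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dyadpredict.fiml import FIMLConvergenceError, fit_fiml_regression
from dyadpredict.simulate import CohortSimConfig, simulate_cohort
from dyadpredict.stats import (
    covariate_screen,
    fit_listwise,
    fit_mice,
    fit_robust,
    little_mcar_test,
    quadratic_check,
    sensitivity_mde,
    sex_moderation,
    simulated_power,
)

COVS = ["mean_hr_bpm", "age_months", "sex", "gestational_age_weeks"]


def complete_cohort(n=300, seed=1, **kw):
    cfg = CohortSimConfig(n=n, missing_rate_range=(0.0, 0.0), seed=seed, **kw)
    return simulate_cohort(cfg)


def mcar_cohort(n=104, seed=1, **kw):
    return simulate_cohort(CohortSimConfig(n=n, seed=seed, **kw))


class TestFIML:
    def test_equals_ols_on_complete_data(self):
        df = complete_cohort()
        res = fit_fiml_regression(df, "rmssd_ms", ["entropy_bits"], COVS)
        cols = ["entropy_bits", *COVS, "rmssd_ms"]
        Z = (df[cols] - df[cols].mean()) / df[cols].std(ddof=0)
        ols = sm.OLS(
            Z["rmssd_ms"], sm.add_constant(Z[["entropy_bits", *COVS]])
        ).fit()
        for term in ["entropy_bits", *COVS]:
            assert res.standardized_betas[term] == pytest.approx(
                float(ols.params[term]), abs=1e-6
            )

    def test_consistency_under_mcar(self):
        df = mcar_cohort(n=10_000, seed=3, beta_entropy_hrv=-0.25)
        res = fit_fiml_regression(df, "rmssd_ms", ["entropy_bits"], COVS)
        assert abs(res.standardized_betas["entropy_bits"] - (-0.25)) < 0.02

    def test_affine_rescaling_invariance(self):
        df = mcar_cohort(n=400, seed=4)
        res1 = fit_fiml_regression(df, "rmssd_ms", ["entropy_bits"], COVS)
        scaled = df.copy()
        scaled["entropy_bits"] = scaled["entropy_bits"] * 12.0 - 3.0
        scaled["rmssd_ms"] = scaled["rmssd_ms"] / 7.0 + 100.0
        res2 = fit_fiml_regression(scaled, "rmssd_ms", ["entropy_bits"], COVS)
        assert res1.standardized_betas["entropy_bits"] == pytest.approx(
            res2.standardized_betas["entropy_bits"], abs=1e-8
        )

    def test_constant_variable_rejected(self):
        df = complete_cohort(n=60)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_fiml_regression(df, "rmssd_ms", ["flat"], [])


class TestRobustnessEstimators:
    def test_all_estimators_agree_without_missingness(self):
        df = complete_cohort(n=250, seed=6)
        args = (df, "rmssd_ms", ["entropy_bits"], COVS)
        b_fiml = fit_fiml_regression(*args).standardized_betas["entropy_bits"]
        b_rob = fit_robust(*args).standardized_betas["entropy_bits"]
        b_lw = fit_listwise(*args).standardized_betas["entropy_bits"]
        b_mice = fit_mice(*args, m=5, seed=0).standardized_betas["entropy_bits"]
        assert b_rob == pytest.approx(b_fiml, abs=1e-6)
        assert b_lw == pytest.approx(b_fiml, abs=1e-4)
        assert b_mice == pytest.approx(b_fiml, abs=1e-4)

    def test_mice_close_to_fiml_under_mcar(self):
        df = mcar_cohort(n=4000, seed=7, missing_rate_range=(0.2, 0.2))
        args = (df, "rmssd_ms", ["entropy_bits"], COVS)
        b_fiml = fit_fiml_regression(*args).standardized_betas["entropy_bits"]
        b_mice = fit_mice(*args, m=8, n_burn=6, seed=1).standardized_betas[
            "entropy_bits"
        ]
        assert abs(b_fiml - b_mice) < 0.03

    def test_robust_se_larger_under_heteroskedasticity(self):
        wins = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.standard_normal(n)
            y = 0.3 * x + np.abs(x) * rng.standard_normal(n)
            df = pd.DataFrame({"x": x, "y": y})
            classical = fit_fiml_regression(df, "y", ["x"]).ses["x"]
            robust = fit_robust(df, "y", ["x"]).ses["x"]
            wins += robust > classical
        assert wins >= 9

    def test_listwise_insufficient_n(self):
        df = mcar_cohort(n=8, seed=1, missing_rate_range=(0.5, 0.6))
        with pytest.raises(ValueError, match="listwise"):
            fit_listwise(df, "rmssd_ms", ["entropy_bits"], COVS)


class TestLittleMCAR:
    VARS = [
        "entropy_bits",
        "rmssd_ms",
        "mean_hr_bpm",
        "sa_duration_s",
        "deceleration_ms",
        "theta_change",
    ]

    def test_complete_data_not_applicable(self):
        df = complete_cohort(n=80)
        res = little_mcar_test(df[self.VARS])
        assert not res.applicable

    def test_mar_missingness_detected(self):
        # missingness driven strongly by an observed variable -> reject often
        rejections = 0
        for seed in range(15):
            df = complete_cohort(n=400, seed=100 + seed)
            drop = df["entropy_bits"] > df["entropy_bits"].median()
            df.loc[drop, "rmssd_ms"] = np.nan
            res = little_mcar_test(df[self.VARS])
            rejections += res.p_value < 0.05
        assert rejections >= 12

    def test_mcar_p_typically_moderate(self):
        res = little_mcar_test(mcar_cohort(n=2000, seed=9)[self.VARS])
        assert res.applicable
        assert res.df > 0
        assert 0.0 <= res.p_value <= 1.0


class TestScreening:
    def test_candidate_equal_to_outcome_selected(self):
        df = complete_cohort(n=200)
        df["cand"] = df["rmssd_ms"]
        selected, _ = covariate_screen(df, ["cand"], ["rmssd_ms"])
        assert selected == ["cand"]

    def test_planted_correlation_power(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 104
            x = rng.standard_normal(n)
            y = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)
            df = pd.DataFrame({"cand": x, "outcome": y})
            selected, _ = covariate_screen(df, ["cand"], ["outcome"])
            hits += "cand" in selected
        assert hits / n_seeds > 0.85

    def test_null_candidate_selection_near_alpha(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame(
                {"cand": rng.standard_normal(200), "outcome": rng.standard_normal(200)}
            )
            selected, _ = covariate_screen(df, ["cand"], ["outcome"])
            hits += "cand" in selected
        assert 0.04 <= hits / n_seeds <= 0.18

    def test_binary_candidate_uses_t_test(self):
        rng = np.random.default_rng(0)
        n = 300
        g = (rng.random(n) < 0.5).astype(float)
        y = 0.8 * g + rng.standard_normal(n)
        df = pd.DataFrame({"cand": g, "outcome": y})
        selected, detail = covariate_screen(df, ["cand"], ["outcome"])
        assert selected == ["cand"]
        assert detail["p"].iloc[0] < 0.01

    def test_constant_candidate_warns_and_skips(self):
        df = complete_cohort(n=60)
        df["flat"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            selected, _ = covariate_screen(df, ["flat"], ["rmssd_ms"])
        assert selected == []


class TestModelChecks:
    def test_planted_quadratic_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 1000
            x = rng.standard_normal(n)
            y = 0.3 * (x**2 - 1) + rng.standard_normal(n)
            df = pd.DataFrame({"x": x, "y": y})
            res = quadratic_check(df, "y", "x")
            hits += res.p_values["x_sq"] < 0.05
        assert hits >= 8

    def test_linear_relation_quadratic_null(self):
        rejections = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.standard_normal(n)
            y = 0.4 * x + rng.standard_normal(n)
            res = quadratic_check(pd.DataFrame({"x": x, "y": y}), "y", "x")
            rejections += res.p_values["x_sq"] < 0.05
        assert rejections <= 5

    def test_constant_focal_errors(self):
        df = pd.DataFrame({"x": np.ones(50), "y": np.random.default_rng(0).standard_normal(50)})
        with pytest.raises(ValueError, match="constant"):
            quadratic_check(df, "y", "x")

    def test_sex_moderation_detects_planted_interaction(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.standard_normal(n)
            sex = (rng.random(n) < 0.5).astype(float)
            y = 0.1 * x + 0.4 * x * (sex - 0.5) + rng.standard_normal(n)
            df = pd.DataFrame({"x": x, "sex": sex, "y": y})
            res = sex_moderation(df, "y", "x")
            hits += res.p_values["x_x_sex"] < 0.05
        assert hits >= 6

    def test_single_sex_errors(self):
        df = pd.DataFrame(
            {
                "x": np.random.default_rng(0).standard_normal(40),
                "sex": np.ones(40),
                "y": np.random.default_rng(1).standard_normal(40),
            }
        )
        with pytest.raises(ValueError, match="both sexes"):
            sex_moderation(df, "y", "x")


class TestSensitivity:
    def test_mde_monotone_decreasing_in_n(self):
        mdes = [sensitivity_mde(n) for n in (50, 104, 500, 5000)]
        assert all(a > b for a, b in zip(mdes, mdes[1:]))
        assert mdes[-1] < 0.05

    def test_mde_at_study_n(self):
        assert sensitivity_mde(104, 0.05, 0.80, 3) >= 0.25

    def test_simulation_matches_analytic_power(self):
        mde = sensitivity_mde(104)
        p_hat = simulated_power(mde, 104, n_reps=1000, seed=5)
        assert abs(p_hat - 0.80) < 0.04

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError, match="n must exceed"):
            sensitivity_mde(5, n_covariates=3)
        with pytest.raises(ValueError, match="alpha and power"):
            sensitivity_mde(104, power=1.2)
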