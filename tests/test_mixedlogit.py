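"""Mixed logistic regression: oracles, fallback ladder, screens."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss

from fncdr.mixedlogit import (FitError, ModelSpec, _NestedLaplace, fit,
                              interaction_screen, predict_linear,
                              significant_set, univariable_screen)
from tests.conftest import simulate_clustered


class TestFit:
    def test_zero_variance_matches_plain_logistic_oracle(self):
        """With no true clustering the mixed fit agrees with an ordinary
        IRLS logistic fit (statsmodels GLM) within 2 standard errors, and
        the estimated random-intercept SDs collapse."""
        tbl = simulate_clustered(seed=10, n_patients=2500,
                                 episodes_per_patient=2, sigma_patient=0.0)
        f = fit(ModelSpec("bacteremia", ("severely_reduced_general_condition",)), tbl)
        X = sm.add_constant(tbl["severely_reduced_general_condition"].to_numpy(dtype=float))
        glm = sm.GLM(tbl["bacteremia"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        for mine, se, ref in zip(f.coefficients, f.standard_errors, glm.params):
            assert abs(mine - ref) < 2.0 * se
        assert f.sigma_patient < 0.1
        assert f.sigma_center < 0.1

    def test_matches_lme4_reference_fit(self):
        """Frozen reference: lme4::glmer on this exact dataset estimates
        intercept -1.1002, slope 0.8542, sigma_center 0.1405,
        sigma_patient 0.4645, logLik -364.78 (three-level Laplace)."""
        rng = np.random.default_rng(3)
        n_pat = 300
        centers = rng.integers(1, 7, n_pat)
        eps = rng.integers(1, 4, n_pat)
        idx = np.repeat(np.arange(n_pat), eps)
        n = idx.size
        x = rng.random(n) < 0.3
        u = 0.4 * rng.standard_normal(6)
        v = 0.9 * rng.standard_normal(n_pat)
        eta = -1.5 + 1.5 * x + u[centers[idx] - 1] + v[idx]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        tbl = pd.DataFrame({
            "center_id": centers[idx], "patient_id": idx + 1,
            "severely_reduced_general_condition": x.astype(int),
            "bacteremia": y.astype(int)})
        f = fit(ModelSpec("bacteremia", ("severely_reduced_general_condition",)), tbl)
        assert f.levels_used == 3
        assert f.coef("intercept") == pytest.approx(-1.1002, abs=0.01)
        assert f.coef("severely_reduced_general_condition") == pytest.approx(0.8542, abs=0.01)
        assert f.sigma_center == pytest.approx(0.1405, abs=0.02)
        assert f.sigma_patient == pytest.approx(0.4645, abs=0.02)
        assert f.loglik == pytest.approx(-364.78, abs=0.05)

    def test_intercept_only_balanced_outcome(self):
        tbl = pd.DataFrame({
            "center_id": 1, "patient_id": np.arange(1, 41),
            "bacteremia": [0, 1] * 20})
        f = fit(ModelSpec("bacteremia", (), grouping="none"), tbl)
        assert f.coef("intercept") == pytest.approx(0.0, abs=1e-6)
        assert f.levels_used == 1

    def test_loglik_never_decreases_with_added_term(self, default_cohort):
        base = fit(ModelSpec("sre", ("severely_reduced_general_condition",),
                             grouping="patient"), default_cohort)
        bigger = fit(ModelSpec("sre", ("severely_reduced_general_condition",
                                       "bone_marrow_involvement"),
                               grouping="patient"), default_cohort)
        if base.levels_used == bigger.levels_used:
            assert bigger.loglik >= base.loglik - 1e-6

    def test_laplace_matches_gauss_hermite_on_one_cluster(self):
        """Laplace vs direct 60-point Gauss-Hermite integration for an
        intercept-only, single-cluster model at fixed parameters."""
        y = np.array([1.0] * 12 + [0.0] * 8)
        X = np.ones((20, 1))
        pc = np.zeros(20, dtype=int)
        sigma, beta = 0.25, 0.3
        m = _NestedLaplace(y, X, None, pc)
        ll_laplace = m.inner_b(np.array([beta]), 0.0, math.log(sigma))
        nodes, weights = hermgauss(60)
        etas = beta + math.sqrt(2.0) * sigma * nodes
        vals = np.array([np.sum(y * e - np.logaddexp(0.0, e)) for e in etas])
        ll_gh = math.log(np.sum(weights * np.exp(vals)) / math.sqrt(math.pi))
        assert ll_laplace == pytest.approx(ll_gh, abs=1e-3)

    def test_single_class_outcome_rejected(self):
        tbl = pd.DataFrame({"center_id": 1, "patient_id": [1, 2, 3],
                            "bacteremia": [0, 0, 0]})
        with pytest.raises(FitError, match="single class"):
            fit(ModelSpec("bacteremia", (), grouping="none"), tbl)

    def test_complete_separation_flagged(self):
        tbl = pd.DataFrame({
            "center_id": 1, "patient_id": np.arange(1, 61),
            "severely_reduced_general_condition": [0, 1] * 30,
            "bacteremia": [0, 1] * 30})
        f = fit(ModelSpec("bacteremia", ("severely_reduced_general_condition",),
                          grouping="none"), tbl)
        assert f.separation
        assert not f.converged
        assert abs(f.coef("severely_reduced_general_condition")) > 10

    def test_fallback_grouping_levels(self, default_cohort):
        for grouping, max_level in (("patient", 2), ("none", 1)):
            f = fit(ModelSpec("sre", ("severely_reduced_general_condition",),
                              grouping=grouping), default_cohort)
            assert f.levels_used <= max_level

    def test_or_equals_exp_coefficient(self, default_cohort):
        f = fit(ModelSpec("sre", ("severely_reduced_general_condition",),
                          grouping="patient"), default_cohort)
        assert np.allclose(f.odds_ratios, np.exp(f.coefficients), atol=1e-10)
        ci = f.or_ci()
        assert np.all(ci[:, 0] <= f.odds_ratios)
        assert np.all(f.odds_ratios <= ci[:, 1])


class TestPredictLinear:
    def test_hand_built_arithmetic(self, default_cohort):
        f = fit(ModelSpec("bacteremia", ("severely_reduced_general_condition",),
                          grouping="none"), default_cohort)
        f.coefficients = np.array([-2.0, 1.56])
        ep = default_cohort.head(4).copy()
        ep["severely_reduced_general_condition"] = [1, 0, 1, 0]
        eta = predict_linear(f, ep)
        assert eta == pytest.approx([-0.44, -2.0, -0.44, -2.0])

    def test_zero_coefficients_give_intercept(self, default_cohort):
        f = fit(ModelSpec("bacteremia", ("severely_reduced_general_condition",),
                          grouping="none"), default_cohort)
        f.coefficients = np.array([-1.3, 0.0])
        assert np.allclose(predict_linear(f, default_cohort), -1.3)

    def test_missing_covariate_named(self, default_cohort):
        f = fit(ModelSpec("bacteremia", ("severely_reduced_general_condition",),
                          grouping="none"), default_cohort)
        with pytest.raises(KeyError):
            predict_linear(f, default_cohort.drop(
                columns=["severely_reduced_general_condition"]))


class TestUnivariableScreen:
    CHARS = ("severely_reduced_general_condition", "bone_marrow_involvement",
             "sex", "cvad", "sirs_at_presentation")

    def test_alpha_one_returns_all_evaluable(self, default_cohort):
        res = univariable_screen(default_cohort, "sre", self.CHARS, alpha=1.0)
        assert significant_set(res) == tuple(
            r.characteristic for r in res if r.evaluable)

    def test_null_type_one_error_rate(self):
        """Outcome independent of candidate covariates: per-characteristic
        rejection rate at alpha=0.05 stays in a sane band."""
        tests = 0
        rejections = 0
        for seed in range(100):
            tbl = simulate_clustered(seed=9000 + seed, n_patients=158,
                                     episodes_per_patient=2, beta=0.0,
                                     sigma_patient=0.8, sigma_center=0.3)
            res = univariable_screen(
                tbl, "bacteremia", ("severely_reduced_general_condition",))
            for r in res:
                if r.evaluable:
                    tests += 1
                    rejections += r.significant
        assert 0.01 <= rejections / tests <= 0.10

    def test_power_for_strong_effect(self):
        """True OR 5 at n≈360: detected in most replications."""
        hits = 0
        reps = 25
        for seed in range(reps):
            tbl = simulate_clustered(seed=2000 + seed, n_patients=158,
                                     episodes_per_patient=2,
                                     beta=math.log(5.0), x_prevalence=0.15,
                                     sigma_patient=0.8, intercept=-2.0)
            res = univariable_screen(
                tbl, "bacteremia", ("severely_reduced_general_condition",))
            hits += res[0].significant
        assert hits / reps > 0.8

    def test_degenerate_fit_does_not_abort_screen(self, default_cohort):
        """A constant covariate (unidentifiable term) must not abort the
        screen: it comes back not-evaluable or non-significant."""
        tbl = default_cohort.copy()
        tbl["sex"] = 0
        res = univariable_screen(tbl, "sre", ("sex", "cvad"))
        assert len(res) == 2
        sex = next(r for r in res if r.characteristic == "sex")
        assert (not sex.evaluable) or (not sex.significant)


class TestInteractionScreen:
    def test_single_fever_limit_level_rejected(self, default_cohort):
        tbl = default_cohort.copy()
        tbl["randomized_fever_limit"] = 38.5
        with pytest.raises(ValueError, match="fever-limit"):
            interaction_screen(tbl, "sre", "severely_reduced_general_condition")

    def test_null_interaction_rarely_significant(self):
        rejections = 0
        reps = 30
        for seed in range(reps):
            tbl = simulate_clustered(seed=3000 + seed, n_patients=180,
                                     episodes_per_patient=2, beta=1.0,
                                     sigma_patient=0.5)
            res = interaction_screen(tbl, "bacteremia",
                                     "severely_reduced_general_condition")
            rejections += res.significant
        assert rejections / reps <= 0.05 + 0.05

    def test_strong_interaction_detected(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            rng = np.random.default_rng(4000 + seed)
            n_pat = 1000
            idx = np.repeat(np.arange(n_pat), 2)
            centers = rng.integers(1, 7, n_pat)
            limit_high = (centers % 2 == 0).astype(float)
            x = (rng.random(idx.size) < 0.3).astype(float)
            v = 0.5 * rng.standard_normal(n_pat)
            eta = -1.0 + 0.3 * x + 2.0 * x * limit_high[idx] + v[idx]
            y = rng.random(idx.size) < 1 / (1 + np.exp(-eta))
            tbl = pd.DataFrame({
                "center_id": centers[idx], "patient_id": idx + 1,
                "severely_reduced_general_condition": x.astype(int),
                "randomized_fever_limit": np.where(limit_high[idx] == 1, 39.0, 38.5),
                "bacteremia": y.astype(int)})
            res = interaction_screen(tbl, "bacteremia",
                                     "severely_reduced_general_condition")
            hits += res.significant
        assert hits / reps > 0.8
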