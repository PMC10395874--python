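"""Score derivation: weights, thresholds, forward selection, internal CV."""

import numpy as np
import pandas as pd
import pytest

from fncdr.derivation import (ForwardSelection, ScoreDefinition, apply_score,
                              calibrate_threshold, derive_rule, derive_weights,
                              forward_select, internal_cv)
from fncdr.mixedlogit import FitResult, ModelSpec
from tests.conftest import simulate_clustered

# printed multivariable coefficients and the integer weights they map to
BACTEREMIA_COEFS = {
    "severely_reduced_general_condition": 1.56,
    "bone_marrow_involvement": 1.41,
    "leucocyte_lt_0_3": 1.69,
    "malignancy_type": {"AML": 1.27, "Hodgkin": -0.30, "NHL": -0.56,
                        "CNS_tumor": -2.58, "other_solid": -1.52},
}
BACTEREMIA_WEIGHTS = {
    "severely_reduced_general_condition": 3,
    "bone_marrow_involvement": 3,
    "leucocyte_lt_0_3": 3,
    "malignancy_type": {"ALL": 5, "AML": 8, "Hodgkin": 4, "NHL": 4,
                        "CNS_tumor": 0, "other_solid": 2},
}
SMC_COEFS = {"severely_reduced_general_condition": 1.90, "platelet_lt_50": 1.11}
SMC_WEIGHTS = {"severely_reduced_general_condition": 4, "platelet_lt_50": 2}
SRE_COEFS = {
    "severely_reduced_general_condition": 1.84,
    "bone_marrow_involvement": 1.23,
    "leucocyte_lt_0_3": 1.54,
    "malignancy_type": {"AML": 0.85, "Hodgkin": -0.89, "NHL": -0.74,
                        "CNS_tumor": -1.85, "other_solid": -1.60},
}
SRE_WEIGHTS = {
    "severely_reduced_general_condition": 4,
    "bone_marrow_involvement": 2,
    "leucocyte_lt_0_3": 3,
    "malignancy_type": {"ALL": 4, "AML": 6, "Hodgkin": 2, "NHL": 3,
                        "CNS_tumor": 0, "other_solid": 1},
}


def fit_from_coefficients(outcome: str, coefs: dict) -> FitResult:
    """Package printed coefficients as a FitResult for weight derivation."""
    labels = ["intercept"]
    values = [-3.0]
    term_columns = {}
    terms = []
    for term, c in coefs.items():
        terms.append(term)
        if isinstance(c, dict):
            cols = []
            for level in ("AML", "Hodgkin", "NHL", "CNS_tumor", "other_solid"):
                cols.append(len(values))
                labels.append(f"{term}[{level}]")
                values.append(c[level])
            term_columns[term] = cols
        else:
            term_columns[term] = [len(values)]
            labels.append(term)
            values.append(c)
    return FitResult(
        spec=ModelSpec(outcome, tuple(terms)), labels=labels,
        coefficients=np.array(values), standard_errors=np.ones(len(values)),
        sigma_center=0.1, sigma_patient=0.5, loglik=0.0, levels_used=3,
        converged=True, term_columns=term_columns)


class TestDeriveWeights:
    @pytest.mark.parametrize("outcome,coefs,weights,max_score", [
        ("bacteremia", BACTEREMIA_COEFS, BACTEREMIA_WEIGHTS, 17),
        ("smc", SMC_COEFS, SMC_WEIGHTS, 6),
        ("sre", SRE_COEFS, SRE_WEIGHTS, 15),
    ])
    def test_printed_weight_columns_reproduced(self, outcome, coefs, weights, max_score):
        sd = derive_weights(fit_from_coefficients(outcome, coefs))
        assert sd.weights == weights
        assert sd.max_score == max_score

    def test_malignancy_offset_is_five_for_bacteremia(self):
        sd = derive_weights(fit_from_coefficients("bacteremia", BACTEREMIA_COEFS))
        assert sd.offsets["malignancy_type"] == 5

    def test_zero_coefficient_gives_zero_weight(self):
        sd = derive_weights(fit_from_coefficients(
            "smc", {"severely_reduced_general_condition": 0.0}))
        assert sd.weights["severely_reduced_general_condition"] == 0

    def test_negative_binary_weight_offsets_within_block(self):
        """A protective binary characteristic scores on absence: the block
        offset moves the weight onto the absent level."""
        sd = derive_weights(fit_from_coefficients(
            "smc", {"severely_reduced_general_condition": -0.6}))
        assert sd.weights["severely_reduced_general_condition"] == 0
        assert sd.offsets["severely_reduced_general_condition"] == 1
        assert sd.max_score == 1
        ep = pd.DataFrame({"severely_reduced_general_condition": [1, 0]})
        assert apply_score(sd, ep).tolist() == [0, 1]

    def test_non_finite_coefficient_rejected(self):
        f = fit_from_coefficients("smc", {"severely_reduced_general_condition": 1.0})
        f.coefficients[1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            derive_weights(f)


@pytest.fixture(scope="module")
def bacteremia_score():
    return derive_weights(fit_from_coefficients("bacteremia", BACTEREMIA_COEFS))


class TestApplyScore:

    def test_worked_example_aml_high_risk(self, bacteremia_score):
        ep = pd.DataFrame({
            "malignancy_type": ["AML"],
            "severely_reduced_general_condition": [1],
            "bone_marrow_involvement": [0],
            "leucocyte_count": [0.2],
        })
        assert apply_score(bacteremia_score, ep)[0] == 8 + 3 + 3

    def test_cns_tumor_no_flags_scores_zero(self, bacteremia_score):
        ep = pd.DataFrame({
            "malignancy_type": ["CNS_tumor"],
            "severely_reduced_general_condition": [0],
            "bone_marrow_involvement": [0],
            "leucocyte_count": [5.0],
        })
        assert apply_score(bacteremia_score, ep)[0] == 0

    def test_smc_score_values_exhaustive(self):
        sd = derive_weights(fit_from_coefficients("smc", SMC_COEFS))
        ep = pd.DataFrame({
            "severely_reduced_general_condition": [0, 0, 1, 1],
            "platelet_count": [100.0, 10.0, 100.0, 10.0],
        })
        assert sorted(apply_score(sd, ep).tolist()) == [0, 2, 4, 6]

    def test_scores_bounded_by_max(self, bacteremia_score, default_cohort):
        s = apply_score(bacteremia_score, default_cohort)
        assert s.min() >= 0
        assert s.max() <= bacteremia_score.max_score

    def test_missing_characteristic_rejected(self, bacteremia_score):
        with pytest.raises((KeyError, ValueError)):
            apply_score(bacteremia_score,
                        pd.DataFrame({"malignancy_type": ["ALL"]}))

    def test_json_round_trip(self, bacteremia_score, default_cohort):
        back = ScoreDefinition.from_json(bacteremia_score.to_json())
        assert np.array_equal(apply_score(back, default_cohort),
                              apply_score(bacteremia_score, default_cohort))


def _counts_to_scores(rows):
    """Expand per-threshold (T, TP, FN) counts of the outcome-positive
    episodes into per-episode scores: TP at threshold T is the number of
    positives scoring >= T, so consecutive rows fix the score bins."""
    rows = sorted(rows)
    scores = [rows[0][0] - 1] * rows[0][2]          # below the first threshold
    for (t, tp, _), (_, tp_next, _) in zip(rows, rows[1:]):
        scores += [t] * (tp - tp_next)              # bin [t, t_next)
    scores += [rows[-1][0]] * rows[-1][1]           # at/above the last
    return np.array(scores), np.ones(len(scores), dtype=bool)


class TestCalibrateThreshold:
    def test_bacteremia_printed_counts_give_five(self):
        # per-threshold confusion counts: T: (TP, FN)
        scores, y = _counts_to_scores([(3, 56, 0), (4, 56, 0), (5, 54, 2), (6, 42, 14)])
        t, warn = calibrate_threshold(scores, y)
        assert (t, warn) == (5, False)

    def test_sre_printed_counts_give_four(self):
        scores, y = _counts_to_scores([(2, 71, 1), (3, 71, 1), (4, 67, 5), (5, 53, 19)])
        t, warn = calibrate_threshold(scores, y)
        assert (t, warn) == (4, False)

    def test_smc_tie_broken_upward(self):
        """Thresholds 1 and 2 are count-identical (score 1 unattainable);
        the larger, more specific cut-off is returned."""
        scores, y = _counts_to_scores([(1, 28, 2), (2, 28, 2), (3, 14, 16)])
        t, warn = calibrate_threshold(scores, y)
        assert (t, warn) == (2, False)

    def test_single_positive_with_max_score(self):
        scores = np.array([0, 1, 3, 6])
        y = np.array([False, False, False, True])
        t, warn = calibrate_threshold(scores, y)
        assert (t, warn) == (6, False)

    def test_unreachable_sensitivity_warns(self):
        scores = np.array([5, 0, 0, 0])
        y = np.array([False, True, True, True])
        # even classifying everything high risk the best threshold is min score
        t, warn = calibrate_threshold(scores, y, min_sensitivity=0.90)
        assert t == 0
        assert not warn  # T=0 classifies all episodes high risk: sens 100%
        t, warn = calibrate_threshold(np.array([1, 2]), np.array([True, False]),
                                      min_sensitivity=2.0)  # impossible target
        assert warn

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([1, 2]), np.array([False, False]))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 18, 400)
        y = rng.random(400) < 0.2
        y[scores.argmax()] = True
        sens_prev, spec_prev = 2.0, -1.0
        for t in range(0, 19):
            sens = np.mean(scores[y] >= t)
            spec = np.mean(scores[~y] < t)
            assert sens <= sens_prev + 1e-12
            assert spec >= spec_prev - 1e-12
            sens_prev, spec_prev = sens, spec


class TestForwardSelect:
    def test_alpha_zero_selects_nothing(self, default_cohort):
        sel = forward_select(default_cohort, "sre",
                             ("severely_reduced_general_condition",),
                             alpha_entry=0.0, guard_reps=2, seed=1)
        assert sel.selected == ()

    def test_empty_candidates_valid(self, default_cohort):
        sel = forward_select(default_cohort, "sre", (), seed=1)
        assert isinstance(sel, ForwardSelection)
        assert sel.selected == ()

    def test_null_candidates_rarely_enter(self):
        """All-null candidates: expected false entries ~ alpha each."""
        sizes = []
        for seed in range(15):
            tbl = simulate_clustered(seed=5000 + seed, n_patients=158,
                                     episodes_per_patient=2, beta=0.0,
                                     sigma_patient=0.8)
            sel = forward_select(tbl, "bacteremia",
                                 ("severely_reduced_general_condition",),
                                 guard_reps=5, seed=seed)
            sizes.append(len(sel.selected))
        assert np.mean(sizes) <= 1.0

    def test_strong_predictor_selected_with_step_log(self):
        tbl = simulate_clustered(seed=77, n_patients=500, episodes_per_patient=2,
                                 beta=1.5, sigma_patient=0.8)
        sel = forward_select(tbl, "bacteremia",
                             ("severely_reduced_general_condition",),
                             guard_reps=5, seed=3)
        assert sel.selected == ("severely_reduced_general_condition",)
        log = sel.step_log()
        assert log.accepted.all()
        assert (log.p_value < 0.05).all()


class TestInternalCV:
    def test_perfectly_separated_toy(self):
        """Score identical to outcome: every fold classifies perfectly."""
        tbl = pd.DataFrame({
            "center_id": 1,
            "patient_id": np.arange(1, 41),
            "severely_reduced_general_condition": [0, 1] * 20,
            "smc": [0, 1] * 20,
        })
        cv = internal_cv(tbl, "smc", ("severely_reduced_general_condition",),
                         reps=2, folds=2, seed=4, refit="logistic")
        assert cv.metrics["sensitivity"]["median"] == 100.0
        assert cv.metrics["specificity"]["median"] == 100.0

    def test_seeded_determinism(self, default_cohort):
        kw = dict(reps=3, folds=5, seed=11, refit="logistic")
        a = internal_cv(default_cohort, "sre",
                        ("severely_reduced_general_condition",), **kw)
        b = internal_cv(default_cohort, "sre",
                        ("severely_reduced_general_condition",), **kw)
        assert a.metrics == b.metrics
        pd.testing.assert_frame_equal(a.per_replication, b.per_replication)

    def test_mixed_refit_ladder_runs(self, default_cohort):
        cv = internal_cv(default_cohort, "sre",
                         ("severely_reduced_general_condition",
                          "bone_marrow_involvement"),
                         reps=2, folds=5, seed=2, refit="mixed")
        assert cv.replications + cv.dropped_replications == 2
        for m in cv.metrics.values():
            if m["median"] is not None:
                assert m["ci_low"] <= m["median"] <= m["ci_high"]

    def test_cv_median_sensitivity_close_to_resubstitution(self, default_cohort):
        """Internal CV is expected to be slightly pessimistic but not
        significantly below the resubstitution estimate."""
        from fncdr.mixedlogit import ModelSpec, fit
        terms = ("severely_reduced_general_condition", "leucocyte_lt_0_3")
        f = fit(ModelSpec("sre", terms), default_cohort)
        rule = derive_rule(f, default_cohort)
        scores = apply_score(rule, default_cohort)
        resub_sens = 100.0 * np.mean(
            scores[default_cohort.sre == 1] >= rule.threshold)
        cv = internal_cv(default_cohort, "sre", terms, reps=10, folds=10,
                         seed=5, refit="logistic")
        assert cv.metrics["sensitivity"]["median"] <= resub_sens + 5.0
        assert cv.metrics["sensitivity"]["median"] >= resub_sens - 15.0
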