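"""Published reference inputs of the study the pipeline re-implements.

``REFERENCE_COEFFICIENTS`` are the multivariable mixed-logistic coefficients
of the three outcome models (log-odds scale; malignancy reference level is
acute lymphoblastic leukemia).  ``REFERENCE_THRESHOLD_COUNTS`` are the
per-threshold (TP, FN) confusion counts of each score on the study cohort,
from which the sensitivity-targeted thresholds are recomputed.

These are inputs to worked examples and re-derivations, not expected
outputs: everything downstream of them is computed by the package.
"""

from __future__ import annotations

import numpy as np

from .mixedlogit import FitResult, ModelSpec

REFERENCE_COEFFICIENTS: dict[str, dict] = {
    "bacteremia": {
        "severely_reduced_general_condition": 1.56,
        "bone_marrow_involvement": 1.41,
        "leucocyte_lt_0_3": 1.69,
        "malignancy_type": {"AML": 1.27, "Hodgkin": -0.30, "NHL": -0.56,
                            "CNS_tumor": -2.58, "other_solid": -1.52},
    },
    "smc": {
        "severely_reduced_general_condition": 1.90,
        "platelet_lt_50": 1.11,
    },
    "sre": {
        "severely_reduced_general_condition": 1.84,
        "bone_marrow_involvement": 1.23,
        "leucocyte_lt_0_3": 1.54,
        "malignancy_type": {"AML": 0.85, "Hodgkin": -0.89, "NHL": -0.74,
                            "CNS_tumor": -1.85, "other_solid": -1.60},
    },
}

#: per-threshold (threshold, TP, FN) of each score on the study cohort
REFERENCE_THRESHOLD_COUNTS: dict[str, list[tuple[int, int, int]]] = {
    "bacteremia": [(3, 56, 0), (4, 56, 0), (5, 54, 2), (6, 42, 14)],
    "smc": [(1, 28, 2), (2, 28, 2), (3, 14, 16)],
    "sre": [(2, 71, 1), (3, 71, 1), (4, 67, 5), (5, 53, 19), (6, 50, 22)],
}

_CATEGORICAL_LEVEL_ORDER = ("AML", "Hodgkin", "NHL", "CNS_tumor", "other_solid")


def reference_fit(outcome: str) -> FitResult:
    """Package the published coefficients as a FitResult so the score
    machinery can be applied to them directly."""
    coefs = REFERENCE_COEFFICIENTS[outcome]
    labels = ["intercept"]
    values = [0.0]
    term_columns: dict[str, list[int]] = {}
    terms: list[str] = []
    for term, c in coefs.items():
        terms.append(term)
        if isinstance(c, dict):
            cols = []
            for level in _CATEGORICAL_LEVEL_ORDER:
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
        coefficients=np.asarray(values, dtype=float),
        standard_errors=np.ones(len(values)),
        sigma_center=0.0, sigma_patient=0.0, loglik=0.0,
        levels_used=3, converged=True, term_columns=term_columns)


def threshold_scores(outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-episode scores and outcome flags of the positive episodes implied
    by the published per-threshold confusion counts (the TP column pins the
    number of positives at or above each threshold)."""
    rows = sorted(REFERENCE_THRESHOLD_COUNTS[outcome])
    scores = [rows[0][0] - 1] * rows[0][2]
    for (t, tp, _), (_, tp_next, _) in zip(rows, rows[1:]):
        scores += [t] * (tp - tp_next)
    scores += [rows[-1][0]] * rows[-1][1]
    return np.asarray(scores), np.ones(len(scores), dtype=bool)
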