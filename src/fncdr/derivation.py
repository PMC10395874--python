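"""From fitted model to integer-points clinical decision rule.

A fitted multivariable model is turned into a score by doubling each
coefficient and rounding half-away-from-zero to an integer; negative weights
within a characteristic's block (e.g. the malignancy-type levels) are removed
by adding the smallest offset that raises the block minimum to zero, the
reference level included.  The rule's threshold is then the largest integer
cut-off whose in-sample sensitivity still reaches the target (>= 90% by
default), i.e. the most specific cut-off compatible with the sensitivity
floor.

Forward selection with an overfitting guard and the replicated k-fold
internal cross-validation (model refit, weight re-derivation and threshold
re-calibration inside every training fold) complete the derivation pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .characteristics import get_characteristic
from .metrics import ConfusionMatrix, auroc, performance
from .mixedlogit import FitError, FitResult, ModelSpec, fit, predict_linear, _plain_logistic, build_design


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class ScoreDefinition:
    """An integer points score: per-characteristic weights, offsets, threshold."""

    outcome: str
    weights: dict  # binary char -> int; categorical char -> {level: int}
    offsets: dict = field(default_factory=dict)  # char -> offset added to its block
    threshold: int | None = None
    max_score: int = 0
    threshold_warning: bool = False
    provenance: dict = field(default_factory=dict)  # coefficients the weights came from

    def to_json(self, **kw) -> str:
        return json.dumps({
            "outcome": self.outcome, "weights": self.weights,
            "offsets": self.offsets, "threshold": self.threshold,
            "max_score": self.max_score, "provenance": self.provenance,
        }, **kw)

    @classmethod
    def from_json(cls, doc: str) -> "ScoreDefinition":
        d = json.loads(doc)
        return cls(outcome=d["outcome"], weights=d["weights"],
                   offsets=d.get("offsets", {}), threshold=d.get("threshold"),
                   max_score=d["max_score"], provenance=d.get("provenance", {}))


def derive_weights(fit_result: FitResult) -> ScoreDefinition:
    """Integer weights from a fitted model (threshold left unset).

    weight = round_half_away_from_zero(2 * coefficient); the reference level
    of a categorical starts at 0; any block containing a negative weight is
    offset so its minimum becomes 0.
    """
    if not np.all(np.isfinite(fit_result.coefficients)):
        raise ValueError("cannot derive weights from non-finite coefficients")
    weights: dict = {}
    offsets: dict = {}
    provenance: dict = {"coefficients": {}}
    for term in fit_result.spec.terms:
        char = get_characteristic(term)
        cols = fit_result.term_columns[term]
        if char.kind == "categorical":
            block = {char.levels[0]: 0}
            for lv, c in zip(char.levels[1:], cols):
                coef = float(fit_result.coefficients[c])
                block[lv] = _round_half_away(2.0 * coef)
                provenance["coefficients"][f"{term}[{lv}]"] = coef
            offset = max(0, -min(block.values()))
            weights[term] = {lv: w + offset for lv, w in block.items()}
            offsets[term] = offset
        else:
            coef = float(fit_result.coefficients[cols[0]])
            w = _round_half_away(2.0 * coef)
            offset = max(0, -w)
            weights[term] = w + offset
            offsets[term] = offset
            provenance["coefficients"][term] = coef
    max_score = sum(max(w.values()) if isinstance(w, dict) else max(w, offsets[t])
                    for t, w in weights.items())
    return ScoreDefinition(outcome=fit_result.spec.outcome, weights=weights,
                           offsets=offsets, max_score=max_score,
                           provenance=provenance)


def apply_score(score: ScoreDefinition, episodes: pd.DataFrame) -> np.ndarray:
    """Integer score of each episode; values lie in [0, max_score]."""
    total = np.zeros(len(episodes), dtype=int)
    for term, w in score.weights.items():
        char = get_characteristic(term)
        if isinstance(w, dict):
            col = episodes[term].astype(str)
            unknown = set(col.unique()) - set(w)
            if unknown:
                raise ValueError(f"{term}: no weight for levels {sorted(unknown)}")
            total += col.map(w).to_numpy(dtype=int)
        else:
            x, _ = char.design(episodes)
            # an offset binary block carries the offset on the absent level
            off = score.offsets.get(term, 0)
            total += off + ((w - off) * x[:, 0]).astype(int)
    return total


def calibrate_threshold(scores, outcome, min_sensitivity: float = 0.90) -> tuple[int, bool]:
    """Largest integer threshold with sensitivity >= ``min_sensitivity``.

    Classifying score >= T as high risk, sensitivity is non-increasing in T,
    so the largest qualifying T is the most specific admissible cut-off.  If
    no threshold qualifies, the minimum observed score is returned with a
    warning flag (everything high risk).

    Returns (threshold, warning_flag).
    """
    scores = np.asarray(scores, dtype=int)
    y = np.asarray(outcome, dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("threshold calibration requires at least one positive outcome")
    best = None
    for t in range(int(scores.min()), int(scores.max()) + 2):
        sens = np.sum((scores >= t) & y) / n_pos
        if sens >= min_sensitivity:
            best = t
    if best is None:
        return int(scores.min()), True
    return best, False


def derive_rule(fit_result: FitResult, episodes: pd.DataFrame,
                min_sensitivity: float = 0.90) -> ScoreDefinition:
    """Weights plus threshold calibrated on ``episodes``."""
    score = derive_weights(fit_result)
    values = apply_score(score, episodes)
    score.threshold, score.threshold_warning = calibrate_threshold(
        values, episodes[score.outcome], min_sensitivity)
    return score


# --------------------------------------------------------------------------
# forward selection with cross-validated AUROC guard

@dataclass
class ForwardStep:
    term: str
    p_value: float
    median_cv_auroc: float
    accepted: bool
    note: str = ""


@dataclass
class ForwardSelection:
    selected: tuple[str, ...]
    steps: list[ForwardStep]

    def step_log(self) -> pd.DataFrame:
        return pd.DataFrame([{"term": s.term, "p_value": s.p_value,
                              "median_cv_auroc": s.median_cv_auroc,
                              "accepted": s.accepted, "note": s.note}
                             for s in self.steps])


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Outcome-stratified episode-level fold assignment."""
    assign = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % n_folds
    return assign


def _cv_auroc(table: pd.DataFrame, outcome: str, terms: tuple[str, ...],
              reps: int, folds: int, seed: int) -> float:
    """Median over replications of the pooled cross-validated AUROC of the
    fixed-effect linear predictor, with fast plain-logistic fold refits."""
    spec = ModelSpec(outcome, terms, grouping="none")
    y, X, _, _, _, _ = build_design(spec, table)
    aurocs = []
    for rep in range(reps):
        rng = substream(seed, "forward_guard", rep)
        assign = _stratified_folds(y, folds, rng)
        pred = np.empty(len(y))
        ok = True
        for k in range(folds):
            tr = assign != k
            if y[tr].min() == y[tr].max():
                ok = False
                break
            beta, _, _, _ = _plain_logistic(y[tr], X[tr])
            pred[~tr] = X[~tr] @ beta
        if ok:
            aurocs.append(auroc(pred, y))
    if not aurocs:
        raise FitError("all guard replications failed")
    return float(np.median(aurocs))


def forward_select(table: pd.DataFrame, outcome: str,
                   candidates: tuple[str, ...],
                   alpha_entry: float = 0.05,
                   guard_reps: int = 100, guard_folds: int = 10,
                   seed: int = 0,
                   grouping: str = "patient_in_center") -> ForwardSelection:
    """Stepwise forward selection, p < alpha_entry for entry, with an
    overfitting guard: an addition that decreases the median cross-validated
    AUROC is rolled back and selection stops."""
    from .mixedlogit import _term_p_value

    selected: list[str] = []
    steps: list[ForwardStep] = []
    prev_auroc = -np.inf
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            try:
                p, _ = _term_p_value(tuple(selected + [cand]), cand, table,
                                     outcome, grouping)
            except (FitError, ValueError) as err:
                steps.append(ForwardStep(cand, float("nan"), float("nan"),
                                         False, f"fit failed: {err}"))
                remaining.remove(cand)
                best = "retry"
                break
            if np.isfinite(p) and (best is None or best == "retry" or p < best[1]):
                best = (cand, p)
        if best == "retry":
            continue
        if best is None or best[1] >= alpha_entry:
            break
        cand, p = best
        med = _cv_auroc(table, outcome, tuple(selected + [cand]),
                        guard_reps, guard_folds, seed)
        if med < prev_auroc:
            steps.append(ForwardStep(cand, p, med, False,
                                     "overfitting guard: median CV AUROC decreased"))
            break
        selected.append(cand)
        remaining.remove(cand)
        steps.append(ForwardStep(cand, p, med, True))
        prev_auroc = med
    return ForwardSelection(tuple(selected), steps)


# --------------------------------------------------------------------------
# replicated internal cross-validation

@dataclass
class CVSummary:
    """Median and percentile 95% CI of each metric across replications."""

    metrics: dict  # name -> {"median": float, "ci_low": float, "ci_high": float}
    replications: int
    folds: int
    per_replication: pd.DataFrame
    dropped_replications: int
    seed: int

    def to_dict(self) -> dict:
        return {"metrics": self.metrics, "replications": self.replications,
                "folds": self.folds, "dropped_replications": self.dropped_replications,
                "seed": self.seed}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def internal_cv(table: pd.DataFrame, outcome: str, selected: tuple[str, ...],
                reps: int = 1000, folds: int = 10,
                min_sensitivity: float = 0.90, seed: int = 0,
                refit: str = "mixed", patient_level_folds: bool = False,
                grouping: str = "patient_in_center") -> CVSummary:
    """Replicated k-fold internal cross-validation of the full derivation.

    Every training fold refits the model (``refit='mixed'`` uses the mixed
    ladder, ``'logistic'`` a fast fixed-effects refit), re-derives the integer
    weights and re-calibrates the threshold on the training episodes; held-out
    episodes are then classified and pooled per replication.  Folds are drawn
    at the episode level with outcome stratification by default;
    ``patient_level_folds`` switches to whole-patient assignment.
    """
    y = table[outcome].to_numpy()
    rows = []
    dropped = 0
    for rep in range(reps):
        rng = substream(seed, "cv_folds", rep)
        if patient_level_folds:
            patients = np.unique(table["patient_id"])
            p_assign = dict(zip(patients,
                                rng.permutation(np.arange(len(patients)) % folds)))
            assign = table["patient_id"].map(p_assign).to_numpy()
        else:
            assign = _stratified_folds(y, folds, rng)
        high = np.zeros(len(y), dtype=bool)
        failed = False
        for k in range(folds):
            tr = assign != k
            train = table.loc[tr]
            if train[outcome].nunique() < 2:
                failed = True
                break
            try:
                if refit == "mixed":
                    f = fit(ModelSpec(outcome, selected, grouping=grouping), train)
                else:
                    f = fit(ModelSpec(outcome, selected, grouping="none"), train)
                rule = derive_rule(f, train, min_sensitivity)
            except (FitError, ValueError):
                failed = True
                break
            held = apply_score(rule, table.loc[~tr])
            high[~tr] = held >= rule.threshold
        if failed:
            dropped += 1
            continue
        cm = ConfusionMatrix.from_predictions(high, y.astype(bool))
        rep_perf = performance(cm)
        rows.append({"replication": rep,
                     "sensitivity": rep_perf.sensitivity.estimate,
                     "specificity": rep_perf.specificity.estimate,
                     "ppv": rep_perf.ppv.estimate,
                     "npv": rep_perf.npv.estimate})
    if not rows:
        raise FitError("every cross-validation replication failed")
    per_rep = pd.DataFrame(rows)
    metrics = {}
    for m in ("sensitivity", "specificity", "ppv", "npv"):
        vals = per_rep[m].dropna().to_numpy(dtype=float)
        if vals.size == 0:  # metric undefined in every replication
            metrics[m] = {"median": None, "ci_low": None, "ci_high": None}
            continue
        metrics[m] = {"median": float(np.median(vals)),
                      "ci_low": float(np.percentile(vals, 2.5)),
                      "ci_high": float(np.percentile(vals, 97.5))}
    return CVSummary(metrics=metrics, replications=len(rows), folds=folds,
                     per_replication=per_rep, dropped_replications=dropped,
                     seed=seed)
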