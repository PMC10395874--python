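"""Diagnostic-performance metrics for binary risk classification.

Confusion-matrix summaries (sensitivity, specificity, PPV, NPV) are reported
in percent with 95% confidence intervals from the Wilson score interval with
continuity correction — the one-sample default of R's ``prop.test``, which is
the convention of the study this pipeline reproduces.  AUROC is the
Mann-Whitney concordance probability with midrank handling of ties, and the
reproducibility comparison between a rule's derivation dataset (DD) and a
validation dataset (VD / rVD) uses the continuity-corrected two-sample
chi-square test of equal proportions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import chi2_contingency, norm, rankdata


def proportion_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float, float]:
    """Point estimate and Wilson continuity-corrected CI, in percent.

    Replicates R ``prop.test(x, n)$conf.int`` exactly, including the cap of
    the continuity correction at ``|x - n/2|`` and the clipping of the bounds
    to [0, 1].

    Returns
    -------
    (estimate, lower, upper) on the 0-100 percent scale.
    """
    successes = int(successes)
    n = int(n)
    if n < 1:
        raise ValueError("proportion_ci requires n >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes={successes} outside [0, {n}]")
    z = norm.ppf((1.0 + confidence) / 2.0)
    est = successes / n
    # prop.test caps the 0.5 continuity correction at |x - E| under p0 = 0.5
    yates = min(0.5, abs(successes - n * 0.5))
    z22n = z * z / (2.0 * n)
    pc = est + yates / n
    if pc >= 1.0:
        upper = 1.0
    else:
        upper = (pc + z22n + z * math.sqrt(pc * (1.0 - pc) / n + z22n / (2.0 * n))) / (1.0 + 2.0 * z22n)
    pc = est - yates / n
    if pc <= 0.0:
        lower = 0.0
    else:
        lower = (pc + z22n - z * math.sqrt(pc * (1.0 - pc) / n + z22n / (2.0 * n))) / (1.0 + 2.0 * z22n)
    return 100.0 * est, 100.0 * max(0.0, lower), 100.0 * min(1.0, upper)


@dataclass(frozen=True)
class ConfusionMatrix:
    """High-risk classification vs outcome: TP, TN, FP, FN counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @staticmethod
    def from_predictions(high_risk, outcome) -> "ConfusionMatrix":
        high_risk = np.asarray(high_risk, dtype=bool)
        outcome = np.asarray(outcome, dtype=bool)
        if high_risk.shape != outcome.shape:
            raise ValueError("high_risk and outcome must have equal length")
        return ConfusionMatrix(
            tp=int(np.sum(high_risk & outcome)),
            tn=int(np.sum(~high_risk & ~outcome)),
            fp=int(np.sum(high_risk & ~outcome)),
            fn=int(np.sum(~high_risk & outcome)),
        )


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage with its 95% CI; ``estimate`` is None when undefined."""

    estimate: float | None
    lower: float | None = None
    upper: float | None = None

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(frozen=True)
class PerformanceReport:
    confusion: ConfusionMatrix
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    low_risk: int
    low_risk_pct: float
    outcome: int
    outcome_pct: float
    auroc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _metric(successes: int, denom: int, confidence: float) -> MetricEstimate:
    if denom == 0:
        return MetricEstimate(None)
    est, lo, hi = proportion_ci(successes, denom, confidence)
    return MetricEstimate(est, lo, hi)


def performance(confusion: ConfusionMatrix, confidence: float = 0.95,
                auroc: float | None = None) -> PerformanceReport:
    """Full performance report from a confusion matrix.

    PPV/NPV with a zero denominator are reported as not-applicable
    (``estimate is None``) rather than 0.
    """
    c = confusion
    if c.positives < 1 or c.negatives < 1:
        raise ValueError("performance requires at least one outcome-positive "
                         "and one outcome-negative episode")
    n = c.n
    return PerformanceReport(
        confusion=c,
        sensitivity=_metric(c.tp, c.positives, confidence),
        specificity=_metric(c.tn, c.negatives, confidence),
        ppv=_metric(c.tp, c.tp + c.fp, confidence),
        npv=_metric(c.tn, c.tn + c.fn, confidence),
        low_risk=c.tn + c.fn,
        low_risk_pct=100.0 * (c.tn + c.fn) / n,
        outcome=c.positives,
        outcome_pct=100.0 * c.positives / n,
        auroc=auroc,
    )


def auroc(scores, outcome) -> float:
    """Concordance probability of ``scores`` for the binary ``outcome``.

    Mann-Whitney rank statistic with ties counted 1/2 via midranks; equals
    the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both outcome classes present")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-tailed p-value of the continuity-corrected chi-square test of
    equal proportions (R ``prop.test`` two-sample behavior)."""
    for v, name in ((n1, "n1"), (n2, "n2")):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("success counts must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    # degenerate margins (all successes or all failures): no evidence either way
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    res = chi2_contingency(table, correction=True)
    return float(res.pvalue)


@dataclass(frozen=True)
class ReproducibilityVerdict:
    """Per-metric and overall reproducibility of a rule vs its derivation data.

    ``overall`` is one of ``both``, ``sensitivity-only``, ``specificity-only``,
    ``neither``, ``not-assessable``.
    """

    sensitivity_reproducible: bool | None
    specificity_reproducible: bool | None
    overall: str
    p_values: dict = field(default_factory=dict)


def _repro_one(dd_x: int, dd_n: int, counts: list[tuple[int, int]], alpha: float) -> tuple[bool, dict]:
    ps = {}
    ok = False
    for label, (x, n) in counts:
        p = two_proportion_test(dd_x, dd_n, x, n)
        ps[label] = p
        ok = ok or p >= alpha
    return ok, ps


def reproducibility_verdict(dd: ConfusionMatrix | None,
                            vd: ConfusionMatrix,
                            rvd: ConfusionMatrix | None = None,
                            alpha: float = 0.05) -> ReproducibilityVerdict:
    """Reproducibility of sensitivity/specificity between derivation (DD) and
    validation (VD, optionally rVD) datasets.

    A metric is reproducible when the two-proportion test is non-significant
    for DD-vs-VD or DD-vs-rVD.  Missing DD counts make the rule
    not-assessable, never a silent pass.
    """
    if dd is None:
        return ReproducibilityVerdict(None, None, "not-assessable")
    comparisons = [("vd", vd)] + ([("rvd", rvd)] if rvd is not None else [])
    sens_ok, sens_p = _repro_one(
        dd.tp, dd.positives,
        [(lbl, (c.tp, c.positives)) for lbl, c in comparisons], alpha)
    spec_ok, spec_p = _repro_one(
        dd.tn, dd.negatives,
        [(lbl, (c.tn, c.negatives)) for lbl, c in comparisons], alpha)
    if sens_ok and spec_ok:
        overall = "both"
    elif sens_ok:
        overall = "sensitivity-only"
    elif spec_ok:
        overall = "specificity-only"
    else:
        overall = "neither"
    return ReproducibilityVerdict(
        sens_ok, spec_ok, overall,
        {"sensitivity": sens_p, "specificity": spec_p})


def round_display(x: float) -> float:
    """One-decimal display rounding, half away from zero (96.35 -> 96.4)."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)
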