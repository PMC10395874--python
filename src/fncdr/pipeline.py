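"""End-to-end workflows: derive-and-cross-validate, and externally validate.

``run_derivation`` chains, per requested outcome: univariable screen →
fever-limit interaction screen (logged) → forward selection with the
overfitting guard → integer weight derivation → threshold calibration →
full-data performance at every attainable threshold → replicated internal
cross-validation.  ``run_external_validation`` scores the registered
published rules on the full table (VD) and each rule's restricted dataset
(rVD) and classifies their reproducibility against user-supplied
derivation-dataset counts.

Every CSV/JSON artifact embeds the run seed and a hash of the configuration,
so identical configurations reproduce byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .characteristics import SCREEN_CHARACTERISTICS
from .cohort import CohortConfig, generate_cohort, read_episodes, validate_episodes
from .derivation import (CVSummary, ScoreDefinition, apply_score, derive_rule,
                         forward_select, internal_cv)
from .metrics import ConfusionMatrix, performance, auroc
from .mixedlogit import FitError, ModelSpec, fit, interaction_screen, significant_set, univariable_screen
from .published import CDR_IDS, read_dd_counts, validate_cdr

log = logging.getLogger("fncdr")


@dataclass
class RunConfig:
    seed: int
    input_path: str | None = None           # CSV of episodes, or simulate:
    cohort: CohortConfig | None = None
    outcomes: tuple[str, ...] = ("bacteremia", "smc", "sre")
    alpha_entry: float = 0.05
    guard_reps: int = 100
    guard_folds: int = 10
    cv_reps: int = 1000
    cv_folds: int = 10
    min_sensitivity: float = 0.90
    cv_refit: str = "mixed"
    cdrs: tuple[str, ...] = CDR_IDS
    dd_counts_path: str | None = None
    outdir: str = "fncdr_out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.min_sensitivity <= 1.0:
            raise ValueError("min_sensitivity must be in (0, 1]")

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("outdir", None)  # output location does not affect the computation
        if doc.get("cohort"):
            doc["cohort"]["episode_count_distribution"] = list(
                doc["cohort"]["episode_count_distribution"])
        payload = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return read_episodes(config.input_path)
    cohort = config.cohort or CohortConfig(seed=config.seed)
    return generate_cohort(cohort)


def _stamp(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


def _threshold_table(rule: ScoreDefinition, scores: np.ndarray,
                     y: np.ndarray) -> pd.DataFrame:
    """Full-data performance at every attainable threshold."""
    rows = []
    auc = auroc(scores, y)
    for t in range(int(scores.min()) + 1, int(scores.max()) + 1):
        cm = ConfusionMatrix.from_predictions(scores >= t, y.astype(bool))
        if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
            continue
        rep = performance(cm)
        rows.append({
            "threshold": t, "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
            "outcome_pct": rep.outcome_pct, "low_risk": rep.low_risk,
            "low_risk_pct": rep.low_risk_pct,
            "sensitivity": rep.sensitivity.estimate,
            "sens_low": rep.sensitivity.lower, "sens_high": rep.sensitivity.upper,
            "specificity": rep.specificity.estimate,
            "spec_low": rep.specificity.lower, "spec_high": rep.specificity.upper,
            "ppv": rep.ppv.estimate, "npv": rep.npv.estimate,
            "auroc": auc, "selected": t == rule.threshold,
        })
    return pd.DataFrame(rows)


@dataclass
class DerivationResult:
    outcome: str
    screen: list
    interactions: pd.DataFrame
    selection: object
    rule: ScoreDefinition | None
    threshold_table: pd.DataFrame | None
    cv: CVSummary | None
    error: str | None = None


def run_derivation(config: RunConfig) -> dict[str, DerivationResult]:
    """The full derivation workflow; one result per requested outcome.

    A stage error aborts that outcome with a structured log entry; other
    outcomes proceed.
    """
    table = _load_table(config)
    validate_episodes(table)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)
    table.to_csv(outdir / "episodes.csv", index=False)
    results: dict[str, DerivationResult] = {}
    for outcome in config.outcomes:
        try:
            results[outcome] = _derive_one(config, table, outcome, outdir, stamp)
        except (FitError, ValueError) as err:
            log.error("outcome %s aborted: %s", outcome, err)
            results[outcome] = DerivationResult(
                outcome, [], pd.DataFrame(), None, None, None, None,
                error=str(err))
    return results


def _derive_one(config: RunConfig, table: pd.DataFrame, outcome: str,
                outdir: Path, stamp: dict) -> DerivationResult:
    if table[outcome].nunique() < 2:
        raise FitError(f"outcome {outcome!r} has a single class in the input")
    log.info("univariable screen for %s", outcome)
    screen = univariable_screen(table, outcome, SCREEN_CHARACTERISTICS)
    candidates = significant_set(screen)
    log.info("%d/%d characteristics significant: %s",
             len(candidates), len(SCREEN_CHARACTERISTICS), candidates)

    inter_rows = []
    for char in candidates:
        try:
            res = interaction_screen(table, outcome, char)
            inter_rows.append({"characteristic": char, "p_value": res.p_value,
                               "significant": res.significant})
        except (FitError, ValueError) as err:
            inter_rows.append({"characteristic": char, "p_value": float("nan"),
                               "significant": False, "error": str(err)})
    interactions = pd.DataFrame(inter_rows)

    selection = forward_select(table, outcome, candidates,
                               alpha_entry=config.alpha_entry,
                               guard_reps=config.guard_reps,
                               guard_folds=config.guard_folds,
                               seed=config.seed)
    if not selection.selected:
        raise FitError("forward selection kept no characteristic")
    final_fit = fit(ModelSpec(outcome, selection.selected), table)
    rule = derive_rule(final_fit, table, config.min_sensitivity)
    scores = apply_score(rule, table)
    ttable = _threshold_table(rule, scores, table[outcome].to_numpy())

    cv = internal_cv(table, outcome, selection.selected,
                     reps=config.cv_reps, folds=config.cv_folds,
                     min_sensitivity=config.min_sensitivity,
                     seed=config.seed, refit=config.cv_refit)

    (outdir / f"score_{outcome}.json").write_text(json.dumps(
        {**json.loads(rule.to_json()), **stamp}, indent=2, sort_keys=True))
    tt = ttable.copy()
    tt["seed"] = stamp["seed"]
    tt["config_hash"] = stamp["config_hash"]
    tt.to_csv(outdir / f"performance_{outcome}.csv", index=False)
    (outdir / f"cv_{outcome}.json").write_text(json.dumps(
        {**cv.to_dict(), **stamp}, indent=2, sort_keys=True))
    sl = selection.step_log()
    sl["seed"] = stamp["seed"]
    sl.to_csv(outdir / f"selection_{outcome}.csv", index=False)
    return DerivationResult(outcome, screen, interactions, selection, rule,
                            ttable, cv)


def run_external_validation(config: RunConfig) -> pd.DataFrame:
    """Validate the selected published rules on VD and rVD; returns the
    S4-style table (one row per rule) and writes CSV + a summary figure."""
    table = _load_table(config)
    validate_episodes(table)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dd = read_dd_counts(config.dd_counts_path) if config.dd_counts_path else {}
    rows = []
    reports = []
    for cdr_id in config.cdrs:
        rep = validate_cdr(cdr_id, table, dd.get(cdr_id))
        reports.append(rep)
        rows.append(rep.row())
    out = pd.DataFrame(rows)
    if len(out):
        stamp = _stamp(config)
        out["seed"] = stamp["seed"]
        out["config_hash"] = stamp["config_hash"]
    out.to_csv(outdir / "external_validation.csv", index=False)
    if reports:
        _scatter_figure(reports, outdir / "figures")
    counts = out["reproducibility"].value_counts().to_dict() if len(out) else {}
    log.info("reproducibility classification counts: %s", counts)
    return out


def _scatter_figure(reports, figdir: Path) -> None:
    """Sensitivity-vs-specificity scatter with CI bars (one point per rule)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 6))
    for rep in reports:
        s = rep.vd.sensitivity
        p = rep.vd.specificity
        if not (s.defined and p.defined):
            continue
        ax.errorbar(p.estimate, s.estimate,
                    xerr=[[p.estimate - p.lower], [p.upper - p.estimate]],
                    yerr=[[s.estimate - s.lower], [s.upper - s.estimate]],
                    fmt="o", capsize=3, label=rep.cdr_id)
    ax.set_xlabel("Specificity (%)")
    ax.set_ylabel("Sensitivity (%)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 105)
    ax.legend(fontsize=7, loc="lower left")
    fig.tight_layout()
    fig.savefig(figdir / "external_validation.png", dpi=150)
    plt.close(fig)
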