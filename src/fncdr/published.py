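"""Registry of eleven published pediatric fever-in-neutropenia decision rules.

Each rule carries its risk-tier function (with the boundary conventions of
the original publication), the eligibility filter that produces the
restricted validation dataset (rVD) — only the in-/exclusion criteria
representable in this schema are applied — and a default mapping of the
rule's target outcome onto this schema's outcome fields.  Composite targets
(adverse events, severe adverse outcomes, invasive bacterial infection,
severe infection complication) default to the safety-relevant-event flag,
ICU-focused targets to the serious-medical-complication flag; the mapping is
explicit configuration, not hard-wired behavior.

Multi-tier rules are binarized low vs intermediate/high for the confusion
metrics; all tiers enter the AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .metrics import (ConfusionMatrix, PerformanceReport, auroc, performance,
                      reproducibility_verdict, ReproducibilityVerdict)

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"
_TIER_ORDER = {LOW: 0, INTERMEDIATE: 1, HIGH: 2}


def _require(episodes: pd.DataFrame, rule_id: str, *columns: str) -> None:
    missing = [c for c in columns if c not in episodes.columns]
    if missing:
        raise KeyError(f"rule {rule_id!r} needs missing predictor(s) {missing}")


@dataclass(frozen=True)
class PublishedCDR:
    id: str
    label: str
    tiers: Callable[[pd.DataFrame], np.ndarray]       # episode table -> tier array
    eligibility: Callable[[pd.DataFrame], np.ndarray]  # -> boolean include mask
    target_outcome: str                                # column of the episode table
    predictors: tuple[str, ...]
    filter_description: str = ""

    def classify(self, episodes: pd.DataFrame) -> np.ndarray:
        _require(episodes, self.id, *self.predictors)
        return self.tiers(episodes)

    def high_risk(self, episodes: pd.DataFrame) -> np.ndarray:
        """Binarized rule: not-low (intermediate or high) vs low."""
        return np.asarray([t != LOW for t in self.classify(episodes)])


# --------------------------------------------------------------------------
# tier functions (boundary comparisons exactly as published)

def _rackoff(t: pd.DataFrame) -> np.ndarray:
    amc = t["amc"].to_numpy(dtype=float)
    temp = t["temperature_at_presentation"].to_numpy(dtype=float)
    out = np.where(amc < 0.1, np.where(temp >= 39.0, HIGH, INTERMEDIATE), LOW)
    return out


def _klaassen(t: pd.DataFrame) -> np.ndarray:
    return np.where(t["amc"].to_numpy(dtype=float) < 0.1, HIGH, LOW)


def _baorto(t: pd.DataFrame) -> np.ndarray:
    return np.where(t["amc"].to_numpy(dtype=float) < 0.155, HIGH, LOW)


def _madsen(t: pd.DataFrame) -> np.ndarray:
    high = ((t["temperature_at_presentation"].to_numpy(dtype=float) >= 39.5)
            & (t["amc"].to_numpy(dtype=float) <= 0.01))
    return np.where(high, HIGH, LOW)


def rondinelli_score(t: pd.DataFrame) -> np.ndarray:
    return (1.0 * (t["age_years"].to_numpy(dtype=float) <= 5.0)
            + 2.0 * t["cvad"].to_numpy(dtype=float)
            + 4.5 * t["clinical_site_infection"].to_numpy(dtype=float)
            + 1.0 * (t["temperature_at_presentation"].to_numpy(dtype=float) > 38.5)
            + 1.0 * (t["hemoglobin"].to_numpy(dtype=float) <= 70.0)
            + 2.5 * t["urti"].to_numpy(dtype=float))


def _rondinelli(t: pd.DataFrame) -> np.ndarray:
    s = rondinelli_score(t)
    # scores below the printed low band (2.5-5) are treated as low risk
    return np.where(s >= 9.0, HIGH, np.where(s >= 5.5, INTERMEDIATE, LOW))


def spog_ae_score(t: pd.DataFrame) -> np.ndarray:
    return (4 * t["chemo_intensity_above_ALL_maintenance"].to_numpy(dtype=int)
            + 5 * (t["hemoglobin"].to_numpy(dtype=float) >= 90.0)
            + 3 * (t["leucocyte_count"].to_numpy(dtype=float) < 0.3)
            + 3 * (t["platelet_count"].to_numpy(dtype=float) < 50.0))


def _spog_ae(t: pd.DataFrame) -> np.ndarray:
    return np.where(spog_ae_score(t) >= 9, HIGH, LOW)


def hakim_score(t: pd.DataFrame) -> np.ndarray:
    mal = t["malignancy_type"].astype(str)
    diag = np.where(mal == "AML", 20,
                    np.where(mal.isin(["ALL", "Hodgkin", "NHL"]), 7, 0))
    return (diag
            + 14 * t["severely_reduced_general_condition"].to_numpy(dtype=int)
            + 11 * (t["temperature_at_presentation"].to_numpy(dtype=float) >= 39.0)
            + 10 * (t["anc"].to_numpy(dtype=float) < 0.1))


def _hakim(t: pd.DataFrame) -> np.ndarray:
    return np.where(hakim_score(t) >= 24, HIGH, LOW)


def _suttitossatam(t: pd.DataFrame) -> np.ndarray:
    return np.where(t["age_years"].to_numpy(dtype=float) >= 10.0, HIGH, LOW)


def aus_score(t: pd.DataFrame) -> np.ndarray:
    return (1 * t["chemo_intensity_above_ALL_maintenance"].to_numpy(dtype=int)
            + 1 * (t["leucocyte_count"].to_numpy(dtype=float) < 0.3)
            + 1 * (t["platelet_count"].to_numpy(dtype=float) < 50.0))


def _aus(t: pd.DataFrame) -> np.ndarray:
    return np.where(aus_score(t) >= 1, HIGH, LOW)


# --------------------------------------------------------------------------
# eligibility filters (rVD)

def _all_eligible(t: pd.DataFrame) -> np.ndarray:
    return np.ones(len(t), dtype=bool)


def _not_inpatient(t: pd.DataFrame) -> np.ndarray:
    return t["inpatient_onset"].to_numpy(dtype=int) == 0


def _klaassen_filter(t: pd.DataFrame) -> np.ndarray:
    return (_not_inpatient(t)
            & (t["new_diagnosis"].to_numpy(dtype=int) == 0)
            & (t["hsct_history"].to_numpy(dtype=int) == 0))


def _baorto_filter(t: pd.DataFrame) -> np.ndarray:
    return ((t["age_years"].to_numpy(dtype=float) >= 1.0)
            & (t["hsct_history"].to_numpy(dtype=int) == 0))


def _madsen_filter(t: pd.DataFrame) -> np.ndarray:
    return _not_inpatient(t) & (t["hsct_history"].to_numpy(dtype=int) == 0)


def _rondinelli_filter(t: pd.DataFrame) -> np.ndarray:
    return (_not_inpatient(t)
            & (t["hsct_history"].to_numpy(dtype=int) == 0)
            & (t["prior_fn_count"].to_numpy(dtype=int) == 0)
            & (t["episode_index"].to_numpy(dtype=int) == 1))


def _hakim_filter(t: pd.DataFrame) -> np.ndarray:
    return _not_inpatient(t) & (t["hsct_history"].to_numpy(dtype=int) == 0)


def _suttitossatam_filter(t: pd.DataFrame) -> np.ndarray:
    return t["age_years"].to_numpy(dtype=float) >= 1.0


def _aus_filter(t: pd.DataFrame) -> np.ndarray:
    return t["hsct_history"].to_numpy(dtype=int) == 0


# --------------------------------------------------------------------------
# the registry

def _cdr(id, label, tiers, elig, outcome, predictors, desc) -> PublishedCDR:
    return PublishedCDR(id=id, label=label, tiers=tiers, eligibility=elig,
                        target_outcome=outcome, predictors=predictors,
                        filter_description=desc)


REGISTRY: dict[str, PublishedCDR] = {c.id: c for c in [
    _cdr("rackoff", "Rackoff 1996", _rackoff, _not_inpatient, "bacteremia",
         ("amc", "temperature_at_presentation"),
         "drop inpatient-onset episodes"),
    _cdr("klaassen", "Klaassen 2000", _klaassen, _klaassen_filter, "bacteremia",
         ("amc",),
         "drop inpatient onset, newly diagnosed, and post-HSCT episodes"),
    _cdr("baorto", "Baorto 2001", _baorto, _baorto_filter, "bacteremia",
         ("amc",),
         "drop age < 1 y and post-HSCT episodes"),
    _cdr("madsen", "Madsen 2002", _madsen, _madsen_filter, "bacteremia",
         ("temperature_at_presentation", "amc"),
         "drop inpatient-onset and post-HSCT episodes"),
    _cdr("rondinelli", "Rondinelli 2006", _rondinelli, _rondinelli_filter, "sre",
         ("age_years", "cvad", "clinical_site_infection",
          "temperature_at_presentation", "hemoglobin", "urti"),
         "drop inpatient onset, post-HSCT, and non-first FN episodes"),
    _cdr("spog_ae", "SPOG-AE (Ammann) 2010", _spog_ae, _not_inpatient, "sre",
         ("chemo_intensity_above_ALL_maintenance", "hemoglobin",
          "leucocyte_count", "platelet_count"),
         "drop inpatient-onset episodes"),
    _cdr("hakim", "Hakim 2010", _hakim, _hakim_filter, "sre",
         ("malignancy_type", "severely_reduced_general_condition",
          "temperature_at_presentation", "anc"),
         "drop inpatient-onset and post-HSCT episodes"),
    _cdr("suttitossatam", "Suttitossatam 2020", _suttitossatam, _suttitossatam_filter,
         "sre", ("age_years",),
         "drop age < 1 y episodes"),
    _cdr("aus_lbi", "AUS (Haeusler) 2020, likely bacterial infection", _aus,
         _aus_filter, "sre",
         ("chemo_intensity_above_ALL_maintenance", "leucocyte_count", "platelet_count"),
         "drop post-HSCT episodes"),
    _cdr("aus_bacteremia", "AUS (Haeusler) 2020, bacteremia", _aus, _aus_filter,
         "bacteremia",
         ("chemo_intensity_above_ALL_maintenance", "leucocyte_count", "platelet_count"),
         "drop post-HSCT episodes"),
    _cdr("aus_icu", "AUS (Haeusler) 2020, ICU admission", _aus, _aus_filter, "smc",
         ("chemo_intensity_above_ALL_maintenance", "leucocyte_count", "platelet_count"),
         "drop post-HSCT episodes"),
]}

CDR_IDS: tuple[str, ...] = tuple(REGISTRY)


def get_cdr(cdr_id: str) -> PublishedCDR:
    try:
        return REGISTRY[cdr_id]
    except KeyError:
        raise KeyError(f"unknown CDR id {cdr_id!r}; known: {sorted(REGISTRY)}")


def classify(cdr_id: str, episodes: pd.DataFrame) -> np.ndarray:
    """Risk tier (low / intermediate / high) of each episode under the rule."""
    return get_cdr(cdr_id).classify(episodes)


def restrict_dataset(cdr_id: str, episodes: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Restricted validation dataset and the number of episodes dropped."""
    cdr = get_cdr(cdr_id)
    mask = cdr.eligibility(episodes)
    return episodes.loc[mask], int((~np.asarray(mask)).sum())


@dataclass
class CDRValidation:
    cdr_id: str
    outcome: str
    vd: PerformanceReport
    rvd: PerformanceReport | None
    rvd_dropped: int
    auroc_all_tiers: float
    reproducibility: ReproducibilityVerdict

    def row(self) -> dict:
        d = {"cdr_id": self.cdr_id, "outcome": self.outcome,
             "auroc": self.auroc_all_tiers,
             "rvd_dropped": self.rvd_dropped,
             "reproducibility": self.reproducibility.overall}
        for block, rep in (("vd", self.vd), ("rvd", self.rvd)):
            if rep is None:
                continue
            c = rep.confusion
            d.update({f"{block}_tp": c.tp, f"{block}_tn": c.tn,
                      f"{block}_fp": c.fp, f"{block}_fn": c.fn,
                      f"{block}_sensitivity": rep.sensitivity.estimate,
                      f"{block}_specificity": rep.specificity.estimate,
                      f"{block}_ppv": rep.ppv.estimate,
                      f"{block}_npv": rep.npv.estimate})
        return d


def validate_cdr(cdr_id: str, episodes: pd.DataFrame,
                 dd_counts: ConfusionMatrix | None = None,
                 target_outcome: str | None = None) -> CDRValidation:
    """External validation of one published rule on VD and rVD.

    The binarized rule (low vs not-low) is scored against the rule's target
    outcome; the AUROC uses all tiers.  ``dd_counts`` (the original
    publication's confusion counts) enable the reproducibility verdict; when
    absent the verdict is not-assessable.
    """
    cdr = get_cdr(cdr_id)
    outcome = target_outcome or cdr.target_outcome
    y = episodes[outcome].to_numpy(dtype=bool)
    high = cdr.high_risk(episodes)
    vd_cm = ConfusionMatrix.from_predictions(high, y)
    tiers = np.array([_TIER_ORDER[t] for t in cdr.classify(episodes)])
    auc = auroc(tiers, y)
    vd = performance(vd_cm, auroc=auc)

    rtable, dropped = restrict_dataset(cdr_id, episodes)
    rvd = None
    rvd_cm = None
    if len(rtable) and rtable[outcome].nunique() == 2:
        rvd_cm = ConfusionMatrix.from_predictions(
            cdr.high_risk(rtable), rtable[outcome].to_numpy(dtype=bool))
        rvd = performance(rvd_cm)
    verdict = reproducibility_verdict(dd_counts, vd_cm, rvd_cm)
    return CDRValidation(cdr_id=cdr_id, outcome=outcome, vd=vd, rvd=rvd,
                         rvd_dropped=dropped, auroc_all_tiers=auc,
                         reproducibility=verdict)


def read_dd_counts(path) -> dict[str, ConfusionMatrix]:
    """Derivation-dataset counts from a CSV with columns cdr_id,tp,tn,fp,fn."""
    tbl = pd.read_csv(path)
    required = {"cdr_id", "tp", "tn", "fp", "fn"}
    if not required <= set(tbl.columns):
        raise ValueError(f"dd_counts CSV must have columns {sorted(required)}")
    out = {}
    for _, r in tbl.iterrows():
        if pd.isna(r[["tp", "tn", "fp", "fn"]]).any():
            continue  # missing published information -> not assessable
        out[r["cdr_id"]] = ConfusionMatrix(int(r.tp), int(r.tn), int(r.fp), int(r.fn))
    return out
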