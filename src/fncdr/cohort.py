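"""Synthetic fever-in-neutropenia cohort generator.

Emulates the structure of a prospective multicenter pediatric oncology FN
study: 6 centers, 158 patients, roughly 360 episodes (1-6 per patient,
median 2), three binary outcomes — bacteremia (~15.6%), serious medical
complications (SMC, ~8.3%) and their union, safety relevant events
(SRE, ~20%) — with risk clustered by patient nested within center via
Gaussian random intercepts on the logit scale.

Outcomes are drawn from logistic models on the episode covariates; the
default fixed-effect coefficients are the multivariable estimates of the
study the pipeline re-implements, and the intercepts ship pre-calibrated so
the marginal prevalences hit their targets.  SMC receives an additive
log-odds boost when bacteremia is present so that the expected overlap
matches the implied 14/360 episodes with both.

Covariates, random intercepts and outcome uniforms are drawn from separate
named substreams of the single seed, so recalibrating an intercept never
perturbs the covariates of the same cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .characteristics import MALIGNANCY_LEVELS, AGE_GROUP_LEVELS


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


class ValidationError(ValueError):
    """An episode table violates the schema; message lists column and rows."""


# --------------------------------------------------------------------------
# configuration

#: episodes-per-patient probability mass over 1..6: median 2, IQR 1-3,
#: mean 2.31 -> about 365 episodes for 158 patients
DEFAULT_EPISODE_PMF = (0.36, 0.28, 0.18, 0.09, 0.05, 0.04)

DEFAULT_COVARIATE_PARAMS: dict = {
    "center_probs": [0.30, 0.22, 0.15, 0.13, 0.10, 0.10],
    "sex_p": 0.55,
    "age_lognorm_median": 6.0,
    "age_lognorm_sigma": 0.8,
    "malignancy_probs": {"ALL": 0.45, "AML": 0.08, "Hodgkin": 0.05,
                         "NHL": 0.10, "CNS_tumor": 0.12, "other_solid": 0.20},
    "relapse_p": 0.12,
    "hsct_history_p": 0.05,
    "chemo_intensity_p": {"ALL": 0.35, "AML": 0.90, "Hodgkin": 0.60,
                          "NHL": 0.60, "CNS_tumor": 0.60, "other_solid": 0.60},
    "cvad_p": 0.80,
    "bone_marrow_p": {"ALL": 0.25, "AML": 0.25, "Hodgkin": 0.10,
                      "NHL": 0.20, "CNS_tumor": 0.02, "other_solid": 0.05},
    "months_since_diagnosis_mean": 12.0,
    "season_p": 0.5,
    "out_of_office_p": 0.6,
    "temperature_shift_mean": 0.2,
    "temperature_shift_sd": 0.5,
    "severely_reduced_p": 0.15,
    "sirs_p": 0.20,
    "hemoglobin_mean": 85.0,
    "hemoglobin_sd": 14.0,
    "leucocyte_lognorm_median": 0.6,
    "leucocyte_lognorm_sigma": 1.0,
    "anc_beta": [2.0, 4.0],
    "amc_beta": [1.5, 8.0],
    "platelet_lognorm_median": 60.0,
    "platelet_lognorm_sigma": 0.9,
    "clinical_site_infection_p": 0.15,
    "urti_p": 0.20,
    "inpatient_onset_p": 0.15,
}

#: multivariable log-odds coefficients of the reference study; zeros for
#: characteristics absent from a model.  Intercepts are pre-calibrated at
#: n_mc=200000 so default marginal prevalences are ~0.156 / 0.083.
DEFAULT_OUTCOME_COEFFICIENTS: dict = {
    "bacteremia": {
        "intercept": None,  # filled below
        "severely_reduced_general_condition": 1.56,
        "bone_marrow_involvement": 1.41,
        "leucocyte_lt_0_3": 1.69,
        "malignancy_type": {"ALL": 0.0, "AML": 1.27, "Hodgkin": -0.30,
                            "NHL": -0.56, "CNS_tumor": -2.58, "other_solid": -1.52},
    },
    "smc": {
        "intercept": None,
        "severely_reduced_general_condition": 1.90,
        "platelet_lt_50": 1.11,
    },
}

# calibrated with calibrate_intercepts(CohortConfig(seed=0), n_mc=200000)
_DEFAULT_INTERCEPTS = {"bacteremia": -2.8173, "smc": -4.0778}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_centers: int = 6
    n_patients: int = 158
    episode_count_distribution: tuple[float, ...] = DEFAULT_EPISODE_PMF
    sigma_center: float = 0.3
    sigma_patient: float = 0.8
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    outcome_coefficients: dict = field(default_factory=lambda: _default_coefficients())
    target_prevalences: dict = field(default_factory=lambda: {"bacteremia": 0.156, "smc": 0.083})
    smc_given_bacteremia_boost: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_centers < 1:
            raise ConfigurationError("n_centers must be >= 1")
        if self.n_patients < self.n_centers:
            raise ConfigurationError("n_patients must be >= n_centers")
        pmf = np.asarray(self.episode_count_distribution, dtype=float)
        if pmf.size != 6 or np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "episode_count_distribution must be 6 non-negative masses summing to 1")
        for name in ("sigma_center", "sigma_patient"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for k, v in self.target_prevalences.items():
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"target_prevalences[{k}] must be in (0,1)")
        probs = self.covariate_params.get("malignancy_probs", {})
        if set(probs) != set(MALIGNANCY_LEVELS):
            raise ConfigurationError("covariate_params.malignancy_probs must cover "
                                     f"{MALIGNANCY_LEVELS}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("covariate_params.malignancy_probs must sum to 1")
        cp = self.covariate_params.get("center_probs")
        if len(cp) != self.n_centers or abs(sum(cp) - 1.0) > 1e-9:
            raise ConfigurationError(
                "covariate_params.center_probs must have n_centers masses summing to 1")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)

    # -- YAML round trip ---------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if "episode_count_distribution" in doc:
            doc["episode_count_distribution"] = tuple(doc["episode_count_distribution"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["episode_count_distribution"] = list(doc["episode_count_distribution"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _default_coefficients() -> dict:
    coefs = {k: dict(v) for k, v in DEFAULT_OUTCOME_COEFFICIENTS.items()}
    coefs["bacteremia"] = dict(coefs["bacteremia"])
    coefs["bacteremia"]["malignancy_type"] = dict(
        DEFAULT_OUTCOME_COEFFICIENTS["bacteremia"]["malignancy_type"])
    for outcome, intercept in _DEFAULT_INTERCEPTS.items():
        coefs[outcome]["intercept"] = intercept
    return coefs


# --------------------------------------------------------------------------
# schema

SCHEMA_COLUMNS: tuple[str, ...] = (
    "center_id", "patient_id", "episode_index",
    "sex", "age_years", "age_group", "malignancy_type", "relapse",
    "chemo_intensity_above_ALL_maintenance", "cvad", "bone_marrow_involvement",
    "months_since_diagnosis", "prior_fn_count", "prior_fn_bacteremia_count",
    "season_spring_summer", "out_of_office_presentation",
    "temperature_at_presentation", "severely_reduced_general_condition",
    "sirs_at_presentation", "randomized_fever_limit",
    "hemoglobin", "leucocyte_count", "anc", "amc", "platelet_count",
    "new_diagnosis", "hsct_history", "clinical_site_infection", "urti",
    "inpatient_onset",
    "bacteremia", "smc", "sre",
)

_BINARY_COLUMNS = (
    "sex", "relapse", "chemo_intensity_above_ALL_maintenance", "cvad",
    "bone_marrow_involvement", "season_spring_summer",
    "out_of_office_presentation", "severely_reduced_general_condition",
    "sirs_at_presentation", "new_diagnosis", "hsct_history",
    "clinical_site_infection", "urti", "inpatient_onset",
    "bacteremia", "smc", "sre",
)


def _age_group(age_years: np.ndarray) -> np.ndarray:
    out = np.where(age_years < 6.0, "<6", np.where(age_years < 12.0, "6-11", ">=12"))
    return out.astype(object)


# --------------------------------------------------------------------------
# generation

def _draw_covariates(config: CohortConfig) -> pd.DataFrame:
    """Covariate table (no outcomes), from the 'covariates' substream."""
    rng = subs = substream(config.seed, "covariates")
    cp = config.covariate_params
    n_pat = config.n_patients

    center = rng.choice(config.n_centers, size=n_pat, p=cp["center_probs"]) + 1
    # cluster randomization of the fever limit: odd centers 38.5, even 39.0
    fever_limit_by_center = {c: (38.5 if c % 2 == 1 else 39.0)
                             for c in range(1, config.n_centers + 1)}
    sex = rng.random(n_pat) < cp["sex_p"]
    age = np.clip(np.exp(np.log(cp["age_lognorm_median"])
                         + cp["age_lognorm_sigma"] * rng.standard_normal(n_pat)),
                  1.0, 17.9)
    mal_levels = list(MALIGNANCY_LEVELS)
    mal_p = [cp["malignancy_probs"][m] for m in mal_levels]
    malignancy = rng.choice(len(mal_levels), size=n_pat, p=mal_p)
    relapse = rng.random(n_pat) < cp["relapse_p"]
    hsct = rng.random(n_pat) < cp["hsct_history_p"]
    chemo = np.array([rng.random() < cp["chemo_intensity_p"][mal_levels[m]]
                      for m in malignancy])
    bm = np.array([rng.random() < cp["bone_marrow_p"][mal_levels[m]]
                   for m in malignancy])

    n_episodes = substream(config.seed, "episode_counts").choice(
        np.arange(1, 7), size=n_pat, p=config.episode_count_distribution)
    idx = np.repeat(np.arange(n_pat), n_episodes)
    n = idx.size
    episode_index = np.concatenate([np.arange(1, k + 1) for k in n_episodes])

    months0 = rng.exponential(cp["months_since_diagnosis_mean"], n_pat)
    months = months0[idx] + (episode_index - 1) * 0.7  # episodes accrue over therapy

    tbl = pd.DataFrame({
        "center_id": center[idx],
        "patient_id": idx + 1,
        "episode_index": episode_index,
        "sex": sex[idx].astype(int),
        "age_years": np.round(age[idx], 2),
        "age_group": _age_group(age[idx]),
        "malignancy_type": np.array(mal_levels, dtype=object)[malignancy[idx]],
        "relapse": relapse[idx].astype(int),
        "chemo_intensity_above_ALL_maintenance": chemo[idx].astype(int),
        "cvad": (rng.random(n) < cp["cvad_p"]).astype(int),
        "bone_marrow_involvement": bm[idx].astype(int),
        "months_since_diagnosis": np.round(months, 1),
        "season_spring_summer": (rng.random(n) < cp["season_p"]).astype(int),
        "out_of_office_presentation": (rng.random(n) < cp["out_of_office_p"]).astype(int),
        "severely_reduced_general_condition":
            (rng.random(n) < cp["severely_reduced_p"]).astype(int),
        "sirs_at_presentation": (rng.random(n) < cp["sirs_p"]).astype(int),
        "new_diagnosis": (months < 2.0).astype(int),
        "hsct_history": hsct[idx].astype(int),
        "clinical_site_infection": (rng.random(n) < cp["clinical_site_infection_p"]).astype(int),
        "urti": (rng.random(n) < cp["urti_p"]).astype(int),
        "inpatient_onset": (rng.random(n) < cp["inpatient_onset_p"]).astype(int),
    })
    limit = tbl["center_id"].map(fever_limit_by_center).to_numpy()
    tbl["randomized_fever_limit"] = limit
    temp = limit + rng.normal(cp["temperature_shift_mean"], cp["temperature_shift_sd"], n)
    tbl["temperature_at_presentation"] = np.round(np.clip(temp, 37.5, 42.0), 1)
    tbl["hemoglobin"] = np.round(np.clip(
        rng.normal(cp["hemoglobin_mean"], cp["hemoglobin_sd"], n), 40.0, 160.0), 0)
    wcc = np.exp(np.log(cp["leucocyte_lognorm_median"])
                 + cp["leucocyte_lognorm_sigma"] * rng.standard_normal(n))
    wcc = np.round(np.clip(wcc, 0.01, 30.0), 2)
    anc_frac = rng.beta(*cp["anc_beta"], n)
    anc = np.round(wcc * anc_frac, 3)
    amc = np.round((wcc - anc) * rng.beta(*cp["amc_beta"], n), 3)
    tbl["leucocyte_count"] = wcc
    tbl["anc"] = anc
    tbl["amc"] = amc
    tbl["platelet_count"] = np.round(np.clip(
        np.exp(np.log(cp["platelet_lognorm_median"])
               + cp["platelet_lognorm_sigma"] * rng.standard_normal(n)),
        1.0, 1000.0), 0)
    assert subs is rng
    return tbl


def _linear_predictor(tbl: pd.DataFrame, coefs: dict) -> np.ndarray:
    """Fixed-effect linear predictor from a coefficient mapping."""
    eta = np.full(len(tbl), float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        if isinstance(beta, dict):  # categorical: per-level log-odds
            eta += tbl[name].map(beta).astype(float).to_numpy()
        elif name in tbl.columns:
            eta += beta * tbl[name].to_numpy(dtype=float)
        elif name == "leucocyte_lt_0_3":
            eta += beta * (tbl["leucocyte_count"] < 0.3).to_numpy(dtype=float)
        elif name == "platelet_lt_50":
            eta += beta * (tbl["platelet_count"] < 50.0).to_numpy(dtype=float)
        elif name == "temperature_ge_39":
            eta += beta * (tbl["temperature_at_presentation"] >= 39.0).to_numpy(dtype=float)
        else:
            raise ConfigurationError(f"outcome_coefficients refers to unknown term {name!r}")
    return eta


def _random_effects(config: CohortConfig, tbl: pd.DataFrame) -> np.ndarray:
    rng = substream(config.seed, "random_effects")
    u = config.sigma_center * rng.standard_normal(config.n_centers)
    v = config.sigma_patient * rng.standard_normal(config.n_patients)
    return (u[tbl["center_id"].to_numpy() - 1]
            + v[tbl["patient_id"].to_numpy() - 1])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic FN-episode table (one row per episode).

    Deterministic given ``config.seed``; the returned table satisfies every
    schema invariant, including ``sre == bacteremia | smc`` exactly.
    """
    config = config or CohortConfig()
    config.validate()
    tbl = _draw_covariates(config)
    re = _random_effects(config, tbl)
    rng = substream(config.seed, "outcome_uniforms")
    u_b = rng.random(len(tbl))
    u_s = rng.random(len(tbl))

    p_b = _sigmoid(_linear_predictor(tbl, config.outcome_coefficients["bacteremia"]) + re)
    bact = u_b < p_b
    eta_s = (_linear_predictor(tbl, config.outcome_coefficients["smc"]) + re
             + config.smc_given_bacteremia_boost * bact)
    smc = u_s < _sigmoid(eta_s)

    tbl["bacteremia"] = bact.astype(int)
    tbl["smc"] = smc.astype(int)
    tbl["sre"] = (bact | smc).astype(int)

    # prior-FN covariates follow from the within-patient episode history
    tbl["prior_fn_count"] = tbl["episode_index"] - 1
    tbl["prior_fn_bacteremia_count"] = (
        tbl.groupby("patient_id")["bacteremia"].cumsum() - tbl["bacteremia"])
    return tbl[list(SCHEMA_COLUMNS)]


# --------------------------------------------------------------------------
# intercept calibration

class CalibrationError(RuntimeError):
    pass


def calibrate_intercepts(config: CohortConfig, n_mc: int = 100_000,
                         tol: float = 0.001, lo: float = -12.0, hi: float = 6.0) -> dict:
    """Per-outcome intercepts hitting ``target_prevalences`` marginally.

    Monte-Carlo estimate of the marginal prevalence (expectation of the
    response probability over covariates and random intercepts) combined with
    monotone bisection on the intercept.  Bacteremia is calibrated first;
    the SMC calibration conditions on bacteremia drawn at the calibrated
    intercept, so the ``smc_given_bacteremia_boost`` is taken into account.
    """
    if n_mc < 10_000:
        raise ValueError("calibrate_intercepts requires n_mc >= 10000")
    # a large synthetic covariate sample from the dedicated calibration stream
    big = config.replace(
        n_patients=max(config.n_centers, int(np.ceil(n_mc / 2.3))),
        seed=config.seed,
    )
    cal_rng = substream(config.seed, "calibration")
    tbl = _draw_covariates(big)
    # marginal prevalence is a per-episode expectation, so integrate over the
    # random-intercept distributions with fresh draws per episode (a handful
    # of realized centers would otherwise bias the calibration)
    re = (big.sigma_center * cal_rng.standard_normal(len(tbl))
          + big.sigma_patient * cal_rng.standard_normal(len(tbl)))

    def solve(eta_rest: np.ndarray, target: float) -> float:
        def prev(intercept: float) -> float:
            return float(np.mean(_sigmoid(intercept + eta_rest)))
        if not prev(lo) <= target <= prev(hi):
            raise CalibrationError(
                f"target {target} not bracketed by intercepts [{lo}, {hi}]")
        a, b = lo, hi
        while b - a > 1e-6:
            m = 0.5 * (a + b)
            if prev(m) < target:
                a = m
            else:
                b = m
        m = 0.5 * (a + b)
        if abs(prev(m) - target) > tol + 0.005:
            raise CalibrationError("bisection failed to reach target prevalence")
        return m

    coefs = config.outcome_coefficients
    targets = config.target_prevalences
    eta_b_rest = _linear_predictor(tbl, {**coefs["bacteremia"], "intercept": 0.0}) + re
    ib = solve(eta_b_rest, targets["bacteremia"])
    bact = cal_rng.random(len(tbl)) < _sigmoid(ib + eta_b_rest)
    eta_s_rest = (_linear_predictor(tbl, {**coefs["smc"], "intercept": 0.0}) + re
                  + config.smc_given_bacteremia_boost * bact)
    i_s = solve(eta_s_rest, targets["smc"])
    return {"bacteremia": round(ib, 4), "smc": round(i_s, 4)}


# --------------------------------------------------------------------------
# CSV I/O with validation

def write_episodes(table: pd.DataFrame, path) -> None:
    validate_episodes(table)
    table.to_csv(path, index=False)


def read_episodes(path) -> pd.DataFrame:
    tbl = pd.read_csv(path)
    validate_episodes(tbl)
    return tbl


def validate_episodes(table: pd.DataFrame) -> None:
    """Raise ValidationError naming column and offending rows on violation."""
    missing = set(SCHEMA_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    extra = set(table.columns) - set(SCHEMA_COLUMNS)
    if extra:
        raise ValidationError(f"unknown columns: {sorted(extra)}")

    def offending(mask, column, rule):
        rows = np.flatnonzero(np.asarray(mask))
        if rows.size:
            raise ValidationError(
                f"column {column!r} violates {rule} at rows {rows[:10].tolist()}")

    for col in _BINARY_COLUMNS:
        offending(~table[col].isin([0, 1]), col, "binary coding 0/1")
    offending(~table["malignancy_type"].isin(MALIGNANCY_LEVELS),
              "malignancy_type", f"levels {MALIGNANCY_LEVELS}")
    offending(~table["age_group"].isin(AGE_GROUP_LEVELS),
              "age_group", f"levels {AGE_GROUP_LEVELS}")
    offending(~table["randomized_fever_limit"].isin([38.5, 39.0]),
              "randomized_fever_limit", "38.5 or 39.0")
    offending(table["sre"] != (table["bacteremia"] | table["smc"]),
              "sre", "sre == bacteremia OR smc")
    offending(table["anc"] > table["leucocyte_count"] + 1e-9,
              "anc", "anc <= leucocyte_count")
    offending(table["temperature_at_presentation"] < 37.5,
              "temperature_at_presentation", ">= 37.5")
    offending(~table["episode_index"].between(1, 6), "episode_index", "1..6")
    for col in ("months_since_diagnosis", "prior_fn_count",
                "prior_fn_bacteremia_count", "hemoglobin", "leucocyte_count",
                "anc", "amc", "platelet_count", "age_years"):
        offending(table[col] < 0, col, ">= 0")
    per_patient = table.groupby("patient_id")["malignancy_type"].nunique()
    bad = per_patient[per_patient > 1]
    if len(bad):
        raise ValidationError(
            f"column 'malignancy_type' not constant within patients {bad.index[:10].tolist()}")
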