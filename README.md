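# fncdr

Derivation, internal cross-validation and external validation of clinical
decision rules (CDRs) for pediatric **fever in neutropenia (FN)** — the
machinery used to build integer-points risk scores that triage children with
cancer presenting with FN into low- versus high-risk groups for three
outcomes: **bacteremia**, **serious medical complications (SMC)** and their
union, **safety relevant events (SRE)**.

The package is aimed at biostatisticians and clinical epidemiologists who
derive or validate diagnostic rules on clustered episode data. It provides:

- a **synthetic cohort generator** emulating a multicenter pediatric
  oncology FN study (6 centers, 158 patients, ~360 episodes, patient- and
  center-level clustering of risk), so every stage is runnable and testable
  without access to patient data;
- **three-level mixed logistic regression** (random intercepts per patient
  nested within centers, Laplace-approximated maximum likelihood, with a
  graceful fallback ladder to two-level and plain logistic fits), plus
  univariable and fever-limit-interaction screens;
- **score derivation**: forward selection with a cross-validated-AUROC
  overfitting guard, integer weights from model coefficients, and
  sensitivity-targeted threshold calibration;
- **replicated k-fold internal cross-validation** in which the model is
  refitted, the weights re-derived and the threshold re-calibrated inside
  every training fold;
- **performance metrics** with the Wilson continuity-corrected 95% CI
  convention (the one-sample default of R's `prop.test`), rank-based AUROC,
  and a reproducibility test comparing validation against derivation
  datasets;
- a **registry of 11 published pediatric FN rules** (Rackoff, Klaassen,
  Baorto, Madsen, Rondinelli, SPOG-AE, Hakim, Suttitossatam, and the three
  AUS rule variants) with their eligibility filters for restricted
  validation datasets (rVD) and an external-validation harness.

## The model and the score

For episode *i* of patient *j* in center *k*, the outcome model is

```
logit P(y_ijk = 1) = x_ijk' β + u_k + v_jk ,   u_k ~ N(0, σ_c²),  v_jk ~ N(0, σ_p²)
```

fitted by Laplace-approximated maximum likelihood. A fitted model becomes a
points score via

```
w = round_half_away_from_zero(2 β)
```

per characteristic, with any block containing a negative weight shifted so
its minimum is zero (the categorical reference level included). The rule's
threshold *T* is the **largest** integer such that classifying score ≥ *T*
as high risk keeps sensitivity ≥ 90% — the most specific cut-off compatible
with the sensitivity floor.

## Worked example

`python examples/derive_score_from_published_model.py` applies the weight
rule to the published multivariable coefficients and prints:

```
bacteremia score (max 17):
  severely_reduced_general_condition: 3
  bone_marrow_involvement: 3
  leucocyte_lt_0_3: 3
  malignancy_type: {'ALL': 5, 'AML': 8, 'Hodgkin': 4, 'NHL': 4, 'CNS_tumor': 0, 'other_solid': 2}
smc score (max 6):
  severely_reduced_general_condition: 4
  platelet_lt_50: 2
sre score (max 15):
  severely_reduced_general_condition: 4
  bone_marrow_involvement: 2
  leucocyte_lt_0_3: 3
  malignancy_type: {'ALL': 4, 'AML': 6, 'Hodgkin': 2, 'NHL': 3, 'CNS_tumor': 0, 'other_solid': 1}

SRE threshold: >= 4 points (largest cut-off keeping sensitivity >= 90%)
```

Reading: a child with AML (8 points) presenting in severely reduced general
condition (3) with leucocytes below 0.3 G/L (3) scores 14 of 17 on the
bacteremia rule — far above the ≥5 threshold, so high risk; a child with a
CNS tumor and no other flags scores 0 and is low risk.

`python examples/simulate_cohort.py` generates one synthetic cohort
(seed 1) and prints:

```
episodes: 361 in 158 patients across 6 centers
episodes per patient: median 2, IQR 1-3, max 6
bacteremia: 54 episodes (15.0%)
smc: 23 episodes (6.4%)
sre: 65 episodes (18.0%)
```

Single cohorts fluctuate around the calibrated marginal rates
(15.6% / 8.3% / 20%); averaging over seeds recovers them.

The other examples run the full derivation + cross-validation chain
(`derive_and_crossvalidate.py`) and the external validation of all eleven
registered rules (`validate_published_rules.py`). A thin CLI wraps the same
workflows: `fncdr simulate`, `fncdr derive`, `fncdr validate-published`.

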