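# Methods

## The statistical model

All association and prediction models are binary-outcome generalized linear
mixed models: three-level mixed logistic regression with random intercepts
per patient nested within centers,

    logit P(y_ijk = 1) = x_ijk' β + u_k + v_jk,
    u_k ~ N(0, σ_c²),   v_jk ~ N(0, σ_p²),

where i indexes the FN episode, j the patient and k the center. Episodes of
one patient share v_jk, episodes of one center share u_k; both effects are
Gaussian on the logit scale and additive.

### Laplace maximum likelihood

The marginal likelihood integrates over all random intercepts. Because the
design is strictly nested, the integral factorizes by center, and the
penalized-likelihood Hessian over the random effects is block-diagonal by
center with *arrow* structure (one center intercept coupled only to its own
patients' intercepts). All inner linear algebra — solves and
log-determinants — therefore runs in time linear in the number of patients.

The fit proceeds in two stages:

1. **Profiled stage**: for each variance pair (σ_c, σ_p), fixed effects and
   random-effect modes are maximized jointly by a damped penalized Newton
   iteration, and the two log-SDs are optimized by L-BFGS-B. This is fast
   but ignores the dependence of the Laplace log-determinant on β.
2. **Full-Laplace refinement**: (β, log σ_c, log σ_p) are then optimized
   jointly over the complete Laplace objective, with only the random-effect
   modes profiled inside. Without this stage the fixed effects carry a
   systematic attenuation (about −0.1 on a log-odds of 1.5 in our
   simulations); with it, estimates, variance components and
   log-likelihoods agree with `lme4::glmer` (Laplace, nAGQ = 1) to ~1e-3 on
   a frozen reference dataset, which one test asserts.

Standard errors of β are the Schur complement of the joint negative Hessian
(conditional on the estimated variances, as in glmer). Wald z-tests give
per-coefficient p-values; multi-level categorical terms are tested by
likelihood ratio at a matched fallback level.

### Fallback ladder and diagnostics

"Model failure" of a level is operationalized as optimizer non-convergence,
a non-finite likelihood, or a random-effect-mode gradient norm above 1e-3
at the returned point. A failed three-level fit is refitted with a
patient-only intercept, then as a plain (damped-Newton/IRLS) logistic
regression; `levels_used` records the outcome. Complete separation is
flagged (|β| > 15) and reported as a diagnostic on the result rather than a
silent estimate; log-SDs are box-constrained to [−6, 3], and a boundary
solution (σ → 0) is a valid fit, not a failure.

## From model to decision rule

- **Weights**: `w = round(2β)` with half-away-from-zero rounding. The
  doubling spreads adjacent coefficients before integer rounding;
  half-away-from-zero is the convention that reproduces every published
  weight from its published coefficient. Offsets that remove negative
  weights are applied per characteristic block — the categorical reference
  level is included in its block, and a negative binary weight moves onto
  the absent level of its own block — never globally.
- **Threshold**: the largest integer T with training sensitivity ≥ the
  target (default 90%). Taking the largest qualifying T (the most specific
  admissible rule) uniquely reproduces the published ≥5 / ≥2 / ≥4 choices,
  including the SMC tie between count-identical cut-offs 1 and 2, broken
  upward. If no cut-off reaches the target, the minimum observed score is
  returned with a warning flag.
- **Forward selection**: candidates are the univariable-significant set;
  the candidate with the smallest entry p-value < 0.05 enters per step.
  After each entry, the median cross-validated AUROC of the fixed-effects
  linear predictor is computed (default 100 replications of 10-fold CV); a
  decrease versus the previous step rolls the entry back and stops
  selection. Guard fold refits are plain logistic fits: the guard scores
  only the fixed-effect predictor, and at guard scale the mixed refit adds
  cost without changing the AUROC ordering.
- **Internal cross-validation**: the full derivation — model refit, weight
  re-derivation, threshold re-calibration — is repeated inside every
  training fold; held-out episodes are pooled per replication, and the
  summary is the median with a 2.5/97.5 percentile interval across
  replications. Folds are episode-level and outcome-stratified by default;
  patient-level folding is available via `patient_level_folds=True`. Fold
  refits use the mixed ladder by default (`refit="logistic"` gives a fast
  fixed-effects variant); a fold whose refit fails even at the bottom of
  the ladder drops its replication, and the count of dropped replications
  is reported.

## Performance metrics

Sensitivity, specificity, PPV and NPV are reported in percent with the
Wilson score interval **with continuity correction** — replicating R
`prop.test`'s one-sample interval bit-for-bit, including the cap of the
correction at |x − n/2| and the clipping of bounds to [0, 1]
(z = 1.959964 at 95%). Undefined ratios (zero denominator for PPV/NPV) are
reported as not-applicable, never as 0. AUROC is the Mann-Whitney
concordance probability with midrank tie handling, equal to the trapezoidal
area under the empirical ROC. The reproducibility comparison between
derivation (DD) and validation (VD/rVD) counts is the continuity-corrected
two-sample chi-square test of equal proportions at α = 0.05 — the cited
function's two-sample behavior; the original study names no test, so this
choice is documented here and isolated in `two_proportion_test`. A rule is
reproducible in a metric if the test is non-significant for DD-vs-VD *or*
DD-vs-rVD; missing DD counts yield "not-assessable", never a silent pass.

Two published performance-table cells contradict their own confusion
counts (a sensitivity CI lower bound of 83.7 where the counts give 83.9,
and an NPV of 91.9 where 220/242 = 90.9 while its printed CI matches the
recomputation); the package reproduces the convention, not the misprints.

## The synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not any real
cohort's joint distribution:

- 6 centers (cluster-randomized fever limit 38.5/39.0 °C), 158 patients,
  episodes per patient drawn from a pmf on 1..6 with median 2, IQR 1–3 and
  mean 2.31 (~365 episodes per cohort);
- patient-level covariates (sex, age, malignancy type, relapse, HSCT
  history, marrow involvement, chemotherapy intensity) and episode-level
  covariates (temperature, blood counts, presentation context) from
  documented parametric defaults chosen for clinical plausibility — e.g.
  ALL the most common malignancy, blood counts log-normal with ~25% of
  episodes below 0.3 G/L leucocytes and ~45% below 50 G/L platelets;
- outcomes from logistic models whose non-intercept coefficients default to
  the published multivariable estimates (zeros for characteristics absent
  from a model), plus center and patient random intercepts
  (σ_c = 0.3, σ_p = 0.8 by default);
- intercepts pre-calibrated by Monte-Carlo bisection (n = 200 000, fresh
  random effects per episode, since marginal prevalence is a per-episode
  expectation) to hit the study's marginal rates of 15.6% bacteremia and
  8.3% SMC;
- SMC receives an additive log-odds boost (default 1.1) when bacteremia is
  present, calibrated so the expected bacteremia∧SMC overlap is ~14 of 360
  episodes — the value implied by 56 + 30 − 72 — which puts the SRE union
  at ~20%. The overlap is a calibration target only; SRE is always computed
  as the exact union.

Covariates, random effects, outcome uniforms, episode counts and every
cross-validation replication draw from separate named substreams of the
single seed, so recalibrating one component never perturbs another.

**What passing tests do not show**: the generator makes no claim about real
covariate correlations (e.g. monocyte count is drawn independently of
outcome, so monocyte-based published rules sit at chance AUROC on synthetic
cohorts), no longitudinal chemotherapy structure, and no time-to-event
information. Pipeline correctness is invariant to these choices; absolute
performance numbers on synthetic cohorts are not study estimates.

## Numerical choices and problem sizes

- Rounding for display: one decimal, half away from zero.
- Age-group boundaries default to <6 / 6–11 / ≥12 years.
- Blood counts enter screens and rules via the dichotomies the rules use
  (leucocytes < 0.3 G/L, platelets < 50 G/L); other continuous
  characteristics enter linearly.
- Composite target outcomes of published rules map onto this schema's SRE
  flag by default, ICU-type targets onto SMC, bacteremia-type onto the
  bacteremia flag; the mapping is per-rule configuration
  (`target_outcome=`), not hard-wired.
- Rondinelli's printed low band (2.5–5) leaves scores below 2.5 unlabeled;
  all scores ≤ 5 are treated as low risk, which is the only consumed
  distinction (low vs not-low).
- Test and acceptance runs use scaled designs chosen to keep the suite
  conveniently re-runnable: parameter recovery uses 200 replications of 400
  patients × 5 episodes; end-to-end recovery uses 50 cohorts of ~2000
  episodes with the four true characteristics plus two null candidates and
  a 10-replication guard; replicated CV examples use 100 instead of 1000
  replications. The statistical claims tested are invariant to these sizes.

## Known limitations

- Laplace (nAGQ = 1) is the only integral approximation; with very small
  clusters (1–3 binary observations) all Laplace-based fits — glmer
  included — carry some small-sample bias in the variance components.
- Random slopes, crossed designs, penalized selection, bootstrap optimism
  correction and probability-scale (non-integer) scores are out of scope.
- The reproducibility verdict depends on the chosen two-proportion test;
  CI-overlap conventions would classify borderline rules differently.
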