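"""Derive a decision rule from data and estimate its performance by
replicated internal cross-validation.

Runs the full derivation chain on a synthetic cohort: univariable screen,
forward selection with the overfitting guard, weight derivation, threshold
calibration, and 100 replications of 10-fold cross-validation (the model is
refitted, the weights re-derived and the threshold re-calibrated inside
every training fold).
"""

from fncdr import CohortConfig, RunConfig, generate_cohort, write_episodes
from fncdr.pipeline import run_derivation

write_episodes(generate_cohort(CohortConfig(seed=11)), "/tmp/episodes.csv")
config = RunConfig(seed=11, input_path="/tmp/episodes.csv",
                   outcomes=("bacteremia",), guard_reps=20, cv_reps=100,
                   cv_refit="logistic", outdir="/tmp/fncdr_example")
result = run_derivation(config)["bacteremia"]

print("selected characteristics:", ", ".join(result.selection.selected))
print(f"threshold: >= {result.rule.threshold} of {result.rule.max_score} points")
print("cross-validated performance (median [95% CI] over 100 replications):")
for name, m in result.cv.metrics.items():
    if m["median"] is None:
        print(f"  {name}: not defined (degenerate classification)")
    else:
        print(f"  {name}: {m['median']:.1f} [{m['ci_low']:.1f}, {m['ci_high']:.1f}]")
print("\nCross-validated sensitivity sits near the 90% target by design; "
      "specificity is what the rule buys at that sensitivity.")
print("A very large max score signals quasi-separation: at ~360 episodes a "
      "rare malignancy level with zero events drives its coefficient, and "
      "hence the block offset, far out. Classification order is unaffected; "
      "the fit carries a separation diagnostic.")
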