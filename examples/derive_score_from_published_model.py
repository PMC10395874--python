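"""Turn published model coefficients into an integer risk score.

Applies the weight rule (2x coefficient, rounded half away from zero,
negative blocks offset to zero) to the published bacteremia model, then
calibrates the threshold of the SRE score on the published per-threshold
confusion counts.
"""

from fncdr.derivation import calibrate_threshold, derive_weights
from fncdr.reference import reference_fit, threshold_scores

for outcome in ("bacteremia", "smc", "sre"):
    score = derive_weights(reference_fit(outcome))
    print(f"{outcome} score (max {score.max_score}):")
    for term, w in score.weights.items():
        print(f"  {term}: {w}")

scores, flags = threshold_scores("sre")
threshold, warn = calibrate_threshold(scores, flags, min_sensitivity=0.90)
print(f"\nSRE threshold: >= {threshold} points "
      f"(largest cut-off keeping sensitivity >= 90%)")
print("\nEach weight is an integer number of points; an episode scoring at "
      "or above the threshold is classified high risk.")
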