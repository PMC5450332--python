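"""Evaluate prediction error with censoring-stratified cross-validation.

Runs 10-fold cross-validation (stratified by censoring status) on a
planted-structure dataset and reports the integrated Brier score (IBS)
of the rule-set model against the Kaplan-Meier-only baseline that
predicts the training-set curve for everyone.  Lower IBS is better; the
rule model should beat the baseline because it separates the two
hazard regimes.
"""

import survrules as sr

dataset, _ = sr.generate(sr.planted_structure_config(n=300, seed=3))

_, rules_agg = sr.cross_validate(
    dataset, sr.InductionConfig(mincov=7), k=10, repeats=1, seed=3, predictor="rules"
)
_, km_agg = sr.cross_validate(
    dataset, sr.InductionConfig(mincov=7), k=10, repeats=1, seed=3, predictor="km"
)

print(f"rule-set model : IBS = {rules_agg.ibs:.4f} "
      f"({rules_agg.n_rules:.1f} rules/fold on average)")
print(f"KM baseline    : IBS = {km_agg.ibs:.4f}")
print("\nIBS is the censoring-weighted squared prediction error averaged "
      "over the follow-up interval; the gap shows the value of the rules.")
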