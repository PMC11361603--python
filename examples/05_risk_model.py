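"""End-to-end cohort: pipeline, propensity classifier, estimation statistics.

Generates two 12-seizure cohorts differing only in shared muscle drive
(kappa 0.8 vs 0.2), runs the whole chain, and prints the classifier report
and bootstrap group effects.  Takes a minute or two.
"""

import warnings

from smanet import PipelineConfig, generate_cohort, run_pipeline

cohort = generate_cohort(4, 4, kappa_a=0.8, kappa_b=0.2,
                         seizures_per_subject=3, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(PipelineConfig(seed=7), [rec for rec, _ in cohort])

print(result.features.groupby("group")[["wpc_low", "wpc_high"]].mean())
clf = result.report["classifier"]
print(f"training AUC:        {clf['training_auc']:.3f}")
print(f"leave-one-out AUC:   {clf['loo_auc']:.3f} over {clf['loo_rounds']} rounds")
print(f"decision threshold:  {clf['decision_threshold']:.3f}")
for band, eff in result.report["group_effects_sudep_minus_non"].items():
    lo, hi = eff["ci95"]
    print(f"{band}: mean WPC difference {eff['mean_difference']:+.4f} "
          f"[95% CI {lo:+.4f}, {hi:+.4f}]")

# Both bands show a positive SUDEP-minus-non difference with CIs excluding
# zero, and the cross-validated AUC says held-out seizures are ranked
# correctly by the propensity score.
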