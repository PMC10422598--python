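"""Emergence proportions, proportion errors and the uniformity verdict.

EP_i = TP_i / ST: the fraction of emerged seedlings at stage i (VE, VC, V1).
A stand is uniform when one stage dominates; substantial coexistence of all
three stages, or low total emergence, makes it non-uniform.
"""

from soyemerge import (StageCounts, emergence_proportion, proportion_error,
                       uniformity_verdict, count_metrics)
from soyemerge.report import CountComparison, UniformityRules

# early-season field: almost everything still at VE
early = emergence_proportion(StageCounts(983, 17, 0), date="day 3")
print(f"{early.date}: EP = {tuple(round(p, 4) for p in early.ep)} -> "
      f"{'uniform' if uniformity_verdict(early).uniform else 'non-uniform'}")

# late-season field: three stages coexist
late = emergence_proportion(StageCounts(45, 41, 14), date="day 10")
verdict = uniformity_verdict(late)
print(f"{late.date}: EP = {tuple(round(p, 4) for p in late.ep)} -> "
      f"non-uniform, reasons: {verdict.reasons}")

# comparing a predicted proportion triple against a manual one
err = proportion_error((0.9380, 0.0261, 0.0359), (0.9830, 0.0170, 0.0))
print(f"per-stage |predicted - real| proportion errors: "
      f"{tuple(round(e, 4) for e in err)}")

# count evaluation over monitoring sites
cmp = CountComparison(real=[52, 61, 48, 70, 66], predicted=[52, 60, 49, 70, 64])
m = count_metrics(cmp)
print(f"count metrics over {cmp.n} sites: R2={m.r2:.4f} RMSE={m.rmse:.2f} "
      f"MAE={m.mae:.2f} average accuracy={m.average_accuracy_pct:.2f}%")
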