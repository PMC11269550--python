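"""Imaging-histology association: ROI q versus synthetic GFAP counts.

The histology subgroup (4 sham / 3 short / 4 long = 11 subjects) gets
GFAP astrocyte counts negatively coupled to day-90 external-capsule q.
Pearson correlation and the least-squares line quantify the association,
and one-way ANOVA + Tukey HSD compares counts across groups.
"""

import numpy as np

from dtiq import (
    CohortSpec,
    generate_cohort,
    generate_ihc_counts,
    oneway_anova_tukey,
    pearson_with_regression,
)
from dtiq.experiments import reduced_phantom

cohort = generate_cohort(reduced_phantom(), CohortSpec(seed=3))
counts = generate_ihc_counts(cohort)

gfap = counts[(counts.stain == "GFAP") & (counts.roi == "EC")]
q = np.array([cohort.truth_roi_q[(s, "day90")]["EC"] for s in gfap["subject_id"]])
corr = pearson_with_regression(q, gfap["count"].to_numpy())
print(f"EC: q vs GFAP over n = {corr.n} subjects")
print(f"  r = {corr.r:.3f}  (p = {corr.p:.4g})")
print(f"  regression: count = {corr.intercept:.1f} + {corr.slope:.3e} * q")

anova, tukey = oneway_anova_tukey(gfap)
print(f"\none-way ANOVA on EC GFAP counts: F({anova.df1},{anova.df2}) = "
      f"{anova.F:.2f}, p = {anova.p:.4g}")
print("Tukey HSD (studentized-range adjusted):")
for _, row in tukey.iterrows():
    mark = "*" if row["significant"] else " "
    print(f"  {row['contrast']:35s} diff = {row['mean_diff']:+7.1f}  "
          f"p_adj = {row['p_adj']:.4g} {mark}")
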