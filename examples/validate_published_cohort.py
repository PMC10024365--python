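"""Rebuild the published validation cohort and re-derive its accuracy metrics.

The 1125-child cohort behind the tool's validation was never deposited, but
its printed marginals (per-score counts, the WHO-malnourished total and the
per-cut-off sensitivity/specificity table) pin down the joint distribution
of score and malnutrition status uniquely.  This script reconstructs it by
exhaustive integer search and runs the full diagnostic validation.
"""

from pednutriscreen import (
    expand_to_records,
    reconstruct_joint_distribution,
    validation_report,
)

dist = reconstruct_joint_distribution()
print("malnourished per score 0-4   :", dist.malnourished)
print("not malnourished per score   :", dist.not_malnourished)
print("metadata                     :", dist.metadata)

cohort = expand_to_records(dist, seed=0)
rep = validation_report(cohort.total_score.to_numpy(float),
                        cohort.who_malnourished.to_numpy(bool))

print("\ncut-off  sens%  spec%  youden%")
for row in rep["cutoff_table"]:
    print(f"{row['cutoff']:>7.1f}  {row['sensitivity_pct']:>5.1f}"
          f"  {row['specificity_pct']:>5.1f}  {row['youden_pct']:>6.1f}")
print(f"\nselected cut-off (max Youden): {rep['selected_cutoff']}")
print(f"sensitivity {rep['sensitivity_pct']}%, specificity "
      f"{rep['specificity_pct']}%, PPV {rep['ppv_pct']}%, NPV {rep['npv_pct']}%")
print(f"Cohen's kappa vs WHO standard: {rep['kappa_rounded']}")
print(f"trapezoidal AUC              : {rep['auc_rounded']}")
print("\nAUC near 1 means the score separates WHO-malnourished from "
      "well-nourished children almost perfectly at some cut-off; the "
      "maximum-Youden rule lands on score >= 2.")
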