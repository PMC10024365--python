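"""Anthropometric z-scores for one child from LMS reference tables.

Builds the bundled synthetic reference library, evaluates the full indicator
set for a 30-month-old boy, and shows the closed-form arithmetic behind one
of the values.
"""

from pednutriscreen import SubjectRecord, synthetic_reference_library, zscore_set

references = synthetic_reference_library()

child = SubjectRecord(
    id="example", sex="male", age_months=30.0,
    weight_kg=9.8, height_cm=65.0, diagnosis_code="n/a",
)
z = zscore_set(child, references)

print(f"weight-for-age z  : {z.wfa:+.2f}")
print(f"height-for-age z  : {z.hfa:+.2f}")
print(f"weight-for-height z: {z.wfh:+.2f}")
print(f"BMI-for-age z     : {z.bmi}  (not applicable under five years)")

# the synthetic tables have L=1 and a linear median, so the z-score is just
# the relative deviation from the median over the coefficient of variation
M = 0.5 * child.height_cm - 21.0  # weight-for-height median at 65 cm
print(f"\ncheck: (w/M - 1)/S = ({child.weight_kg}/{M} - 1)/0.11 "
      f"= {(child.weight_kg / M - 1) / 0.11:+.2f}")
print("negative values sit below the reference median; z < -2 marks a deficit.")
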