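"""Score one hospitalized child with the three-component malnutrition-risk tool.

Disease risk (0-1) comes from the diagnosis registry, dietary intake (0-2)
from the reported change in eating, and the anthropometric subscore (0-3)
from the weight-for-height (or BMI-for-age) z.  A total of 2 or more flags
the child as at risk of malnutrition.
"""

from pednutriscreen import (
    SubjectRecord,
    bundled_registry,
    screen,
    synthetic_reference_library,
)

registry = bundled_registry()
references = synthetic_reference_library()

child = SubjectRecord(
    id="case-1", sex="female", age_months=7.0,
    weight_kg=4.9, height_cm=53.5,
    diagnosis_code="Tetralogy of Fallot",
    dietary_intake="normal",
)

result = screen(child, registry, references)
print(f"disease risk subscore : {result.disease_score}  (tier-1 lesion)")
print(f"dietary intake        : {result.diet_score}")
print(f"anthropometric        : {result.anthro_score}  "
      f"(weight-for-height z = {result.anthro_z:+.2f})")
print(f"total score           : {result.total} / 6")
print(f"at risk (score >= {result.threshold}) : {result.at_risk}")
print("\nAn at-risk flag routes the child to a registered dietitian for a "
      "full nutrition assessment.")
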