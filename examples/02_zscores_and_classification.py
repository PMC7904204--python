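"""Compute LMS z-scores from a growth reference and classify undernutrition.

A measurement x maps to z = ((x/M)^L - 1)/(L*S) (log form when L = 0) using
the reference's L, M, S parameters for the child's sex, age and indicator.
Thinness is BMI-for-age z < -2; stunting is height-for-age z <= -2; their
co-existence flags both in one adolescent.
"""

from healthineq import (
    classify_nutrition,
    compute_bmi,
    lms_zscore,
    load_reference,
    lookup_reference,
    make_lms_fixture,
)

reference = load_reference(make_lms_fixture())  # synthetic test reference

sex, age_months, height_cm, weight_kg = "girl", 150, 132.0, 24.0
bmi = compute_bmi(weight_kg, height_cm)
print(f"{sex}, {age_months} months, {height_cm} cm, {weight_kg} kg -> BMI {bmi:.2f} kg/m²")

L, M, S = lookup_reference(reference, sex, age_months, "bmi_age")
z_bmi = lms_zscore(bmi, L, M, S)
L, M, S = lookup_reference(reference, sex, age_months, "height_age")
z_haz = lms_zscore(height_cm, L, M, S)
print(f"BMI-for-age z = {z_bmi:.2f}   height-for-age z = {z_haz:.2f}")

status = classify_nutrition(z_bmi, z_haz)
print(f"thinness={status.thinness}  stunting={status.stunting}  both={status.both}")

# Note the asymmetric boundary: a z-score of exactly -2 counts as stunted
# (height-for-age <= -2) but not as thin (BMI-for-age strictly < -2).
print("at z = -2 exactly:", classify_nutrition(-2.0, -2.0))
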