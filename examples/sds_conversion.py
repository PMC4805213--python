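"""Convert a child's measurements to standard deviation scores (SDS).

Builds the packaged synthetic growth reference and scores one girl's height,
BMI and head circumference against it.  An SDS of 0 is the population median
for age and sex; +2.0 is the conventional tall-stature boundary.
"""

from tallstature import MeasurementKind, Sex, synthetic_reference

ref = synthetic_reference()

age, sex = 9.4, Sex.FEMALE
height_cm, weight_kg, hc_cm = 145.4, 33.5, 54.0

hsds = ref.sds(height_cm, age, sex, MeasurementKind.HEIGHT)
bmi = weight_kg / (height_cm / 100) ** 2
bmi_sds = ref.sds(bmi, age, sex, MeasurementKind.BMI)
hc_sds = ref.sds(hc_cm, age, sex, MeasurementKind.HEAD_CIRCUMFERENCE)

print(f"girl, {age} y, {height_cm} cm")
print(f"  height SDS          : {hsds:+.2f}")
print(f"  BMI SDS             : {bmi_sds:+.2f}")
print(f"  head circumference  : {hc_sds:+.2f}")
print()
print("height SDS above +2.00 would classify the child as tall;")
print("head circumference above +2.00 would flag macrocephaly.")
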