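"""Target height and adult height prediction for a tall boy.

Computes the Tanner midparental and conditional target heights, predicts
adult height with the De Waal regression (current height, conditional target
height SDS, chronological age, bone age), and screens the prediction against
the 205 cm surgical-counselling threshold for boys.
"""

from tallstature import (
    Sex,
    conditional_target_height,
    epiphysiodesis_indicated,
    pah_de_waal,
    synthetic_reference,
    tanner_target_height,
)

ref = synthetic_reference()

father, mother = 193.0, 178.0
height, ca, ba = 172.0, 12.0, 13.0

th = tanner_target_height(father, mother, Sex.MALE)
cth = conditional_target_height(father, mother, Sex.MALE)
cth_sds = ref.adult_sds(cth, Sex.MALE)
pah = pah_de_waal(height, cth_sds, ca, ba, Sex.MALE)

print(f"parents {father:.0f}/{mother:.0f} cm -> Tanner TH {th:.1f} cm, "
      f"conditional TH {cth:.1f} cm ({cth_sds:+.2f} SDS)")
print(f"boy {ca} y, {height} cm, bone age {ba} y")
print(f"  predicted adult height (De Waal): {pah:.1f} cm "
      f"({ref.adult_sds(pah, Sex.MALE):+.2f} SDS)")
print(f"  epiphysiodesis screen (>205 cm) : "
      f"{'positive' if epiphysiodesis_indicated(pah, Sex.MALE) else 'negative'}")
print()
print("the prediction falls with advancing bone age: less growth remains.")
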