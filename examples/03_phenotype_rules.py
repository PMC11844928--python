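"""Phenotype derivation rules on hand-picked inputs.

Shows blood-pressure censoring, BMI, the Friedewald LDL-C formula with its
TG<400 validity bound, and the NIAAA drinking classification.
"""

import pegskit as pk

# Blood pressure: a 260 mmHg SBP reading is an artifact and is censored,
# but its paired DBP reading survives (channels are independent).
sbp, dbp = pk.process_blood_pressure([(260, 80), (120, 82)])
print(f"BP from readings (260/80), (120/82): SBP={sbp:.0f}, DBP={dbp:.0f}")

print(f"BMI for 70 kg, 1.70 m: {pk.compute_bmi(70, 1.70):.2f} kg/m2")

print(f"Friedewald LDL (TC=200, HDL=50, TG=150): "
      f"{pk.friedewald_ldl(200, 50, 150):.0f} mg/dL")
print(f"Friedewald LDL at TG=400: {pk.friedewald_ldl(200, 50, 400)} "
      f"(undefined at or above 400 mg/dL)")

# NIAAA: 10.5 drinks/week = 1.5/day. Heavy for women and for anyone over
# 65; moderate for a 60-year-old man (cutoff 2/day).
for age, sex in [(60, "male"), (70, "male"), (60, "female")]:
    print(f"10.5 drinks/week, {sex} aged {age}: "
          f"{pk.classify_drinker(10.5, age, sex)}")
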