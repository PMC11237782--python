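"""Show how cachexia dominates the recommendation.

A sarcopenic patient meeting the inflammatory triad (CRP > 10 mg/L,
transferrin < 150 mg/dL, albumin < 3.5 g/dL) is cachectic; the engine then
forces the 1.8 energy factor, the 25% protein share and both supplements,
regardless of BMI and COPD stage.
"""

import nutricopd as nc

base = {
    "id": "cachectic", "gender": "male", "age": 70,
    "current_weight": 58, "usual_weight": 68, "height": 1.72,
    "fev1_percent": 85, "hand_grip": 18, "gait_speed": 0.6,
    "resistance": 900, "reactance": 35,
    "albumin": 3.1, "crp": 22.0, "transferrin": 120,
}
cls, rec, trace = nc.recommend(nc.validate_patient(base))

print(f"sarcopenia: {cls.sarcopenia_level.value}, cachectic: {cls.cachectic}")
print(f"energy factor: {rec.energy_kcal / rec.bmr_kcal:.1f} "
      f"(stage {cls.copd_stage.value} alone would give 1.5)")
print(f"protein share: {rec.protein_share:.0f}% "
      f"({rec.protein_g:.0f} g at {rec.energy_kcal} kcal/day)")
print(f"BCAA: {rec.bcaa_supplement}, "
      f"energy-protein supplement: {rec.energy_protein_supplement}")
print("rules that fired for the energy target:",
      ", ".join(trace.rules_for("energy_kcal")))
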