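"""Classify one patient and walk through the full 14-item recommendation.

A 64-year-old normal-weight man with moderate (stage II) COPD: the engine
picks the Harris-Benedict equation (BMR 1470 kcal), applies the stage-I/II
correction factor 1.5 (2205 kcal/day total), sets protein at 1.2 g/kg
(84 g, ~15% of energy), carbohydrate at 45-50% and fat as the remainder,
plus the sugar/saturated-fat/cholesterol/sodium caps.
"""

import nutricopd as nc

patient = nc.validate_patient({
    "id": "walkthrough", "gender": "male", "age": 64,
    "current_weight": 70, "usual_weight": 70, "height": 1.75,
    "fev1_percent": 65, "hand_grip": 40, "gait_speed": 1.2,
    "resistance": 500, "reactance": 50,
    "albumin": 4.0, "crp": 2.0, "transferrin": 250,
})

classification, recommendation, trace = nc.recommend(patient)

print("classification:")
print(f"  phenotype        {classification.phenotype.value}"
      f"  (BMI {classification.bmi:.2f} kg/m²)")
print(f"  COPD stage       {classification.copd_stage.value}")
print(f"  NRI              {classification.nri_value:.2f}"
      f" → {classification.nri_class.value} risk")
print(f"  ASMM             {classification.asmm:.2f} kg"
      f"  (RI {classification.resistive_index:.2f} cm²/Ω)")
print(f"  sarcopenia       {classification.sarcopenia_level.value}"
      f"   cachectic: {classification.cachectic}")
print("recommendation:")
print(f"  BMR              {recommendation.bmr_kcal} kcal/day")
print(f"  total energy     {recommendation.energy_kcal} kcal/day"
      f"  (factor {recommendation.energy_kcal / recommendation.bmr_kcal:.1f})")
print(f"  protein          {recommendation.protein_g:.0f} g"
      f"  ({recommendation.protein_share:.1f}% of energy)")
print(f"  carbohydrate     {recommendation.carb_share_min:.0f}-"
      f"{recommendation.carb_share_max:.0f}%"
      f"  ({recommendation.carb_g_min:.0f}-{recommendation.carb_g_max:.0f} g)")
print(f"  fat              {recommendation.fat_share_min:.1f}-"
      f"{recommendation.fat_share_max:.1f}%"
      f"  ({recommendation.fat_g_min:.0f}-{recommendation.fat_g_max:.0f} g)")
print(f"  sugar ≤          {recommendation.sugar_share_max:.0f}%"
      f"  ({recommendation.sugar_g_max:.0f} g)")
print(f"  saturated fat ≤  {recommendation.satfat_share_max:.0f}%"
      f"  ({recommendation.satfat_g_max:.0f} g)")
print(f"  cholesterol ≤    {recommendation.cholesterol_max_mg:.0f} mg,"
      f" sodium ≤ {recommendation.sodium_max_mg:.0f} mg,"
      f" calcium {recommendation.calcium_mg:.0f} mg")
print(f"  fiber            {recommendation.fiber_min_g:.0f}-"
      f"{recommendation.fiber_max_g:.0f} g")
print(f"  meals/day        {recommendation.meals_per_day},"
      f" BCAA: {recommendation.bcaa_supplement},"
      f" energy-protein suppl.: {recommendation.energy_protein_supplement}")
print(f"({len(trace.entries)} rules fired; each output field is traceable "
      f"to the rule and provenance that set it)")
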