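# Editable rule base for the COPD nutrition engine.
#
# Every clinical constant the engine uses lives here, one row per rule with a
# stable id and a provenance tag:
#   published  — taken from the clinical rule base / guidelines the engine encodes
#   assumption — implementation choice where the rule base gives direction but no number
#
# Decision-table sections (energy.correction_factors, protein.rules,
# supplements.rules) use first-match semantics over a context of
# {phenotype, stage, sarcopenic, cachectic}; `when: {}` matches everything.
# Phenotype obesity_3 is routed to the obesity_2 rule branch before matching
# (the rule base defines five phenotype branches).

constants:
  nri:
    # NRI = 1.519 x albumin(g/L) + 41.7 x current/usual weight ratio
    albumin_g_per_l_coeff: 1.519
    weight_ratio_coeff: 41.7
  asmm:
    # Sergi BIA equation: ASMM(kg) = -3.964 + 0.227*RI + 0.095*kg + 1.384*male + 0.064*Xc
    intercept: -3.964
    resistive_index: 0.227
    weight: 0.095
    male_offset: 1.384
    reactance: 0.064
  bmr:
    harris_benedict:
      male: {intercept: 66.5, weight: 13.75, height_cm: 5.0, age: 6.78}
      female: {intercept: 655.1, weight: 9.563, height_cm: 1.850, age: 4.676}
    mifflin:
      weight: 10.0
      height_cm: 6.25
      age: 5.0
      male_offset: 5.0
      female_offset: -161.0

cutoffs:
  copd_stage:           # FEV1 % predicted, Table-style half-open bands
    - {stage: I, min: 80}
    - {stage: II, min: 50, max: 80}
    - {stage: III, min: 30, max: 50}
    - {stage: IV, max: 30}
  bmi_phenotype:        # WHO BMI bands, kg/m2, upper bound exclusive
    - {phenotype: underweight, max: 18.5}
    - {phenotype: normal_weight, min: 18.5, max: 25.0}
    - {phenotype: overweight, min: 25.0, max: 30.0}
    - {phenotype: obesity_1, min: 30.0, max: 35.0}
    - {phenotype: obesity_2, min: 35.0, max: 40.0}
    - {phenotype: obesity_3, min: 40.0}
  nri_class:            # absence > 100; mild closed [97.5, 100]; moderate [83.5, 97.5); severe < 83.5
    - {cls: absence, min_exclusive: 100}
    - {cls: mild, min: 97.5, max_inclusive: 100}
    - {cls: moderate, min: 83.5, max: 97.5}
    - {cls: severe, max: 83.5}
  sarcopenia:
    hand_grip_kg: {male: 27, female: 16}          # criterion 1: low strength, grip < cutoff
    asmm_kg: {male: 20, female: 15}               # criterion 2a: low absolute muscle mass
    asmm_over_height2: {male: 7.0, female: 5.5}   # criterion 2b: low ASMM/height^2, kg/m2
    gait_speed_max: 0.8                           # criterion 3: poor performance, <= cutoff m/s
  cachexia:
    crp_above: 10          # mg/L, strict >
    transferrin_below: 150 # mg/dL, strict <
    albumin_below: 3.5     # g/dL, strict <

energy:
  correction_factors:
    - id: energy.factor.cachectic
      when: {cachectic: true}
      factor: 1.8
      provenance: published
      description: cachexia always takes the 1.8 factor regardless of BMI and stage
    - id: energy.factor.stage_3_4
      when: {stage: [III, IV]}
      factor: 1.8
      provenance: published
      description: stage III/IV COPD raises the factor to 1.8 for the respiratory work
    - id: energy.factor.stage_1_2
      when: {stage: [I, II]}
      factor: 1.5
      provenance: published
      description: stage I/II COPD uses the 1.5 factor, sarcopenic or not

protein:
  reference_bmi: 22.5   # kg/m2, target BMI used for underweight patients
  ideal_bmi: 25.0       # kg/m2, ideal-weight basis for obese branches
  cachectic_share: 25   # % of energy, fixed share for cachectic patients
  rules:
    - id: protein.cachectic
      when: {cachectic: true}
      method: fixed_share
      provenance: published
      description: cachectic patients get a fixed 25% protein share
    - id: protein.sarcopenic.underweight
      when: {sarcopenic: true, phenotype: [underweight]}
      method: per_kg
      g_per_kg: 1.5
      basis: reference_bmi
      provenance: assumption
      description: sarcopenic underweight, 1.5 g/kg of the 22.5-BMI reference weight
    - id: protein.sarcopenic.normal_overweight
      when: {sarcopenic: true, phenotype: [normal_weight, overweight]}
      method: per_kg
      g_per_kg: 1.5
      basis: current_weight
      provenance: assumption
      description: sarcopenic normal/overweight, 1.5 g/kg current weight
    - id: protein.sarcopenic.obese
      when: {sarcopenic: true, phenotype: [obesity_1, obesity_2]}
      method: per_kg
      g_per_kg: 1.5
      basis: ideal_bmi
      provenance: assumption
      description: sarcopenic obese, 1.5 g/kg of the 25-BMI ideal weight
    - id: protein.underweight
      when: {phenotype: [underweight]}
      method: per_kg
      g_per_kg: 1.2
      basis: reference_bmi
      provenance: published
      description: underweight, 1.2 g/kg of the 22.5-BMI reference weight
    - id: protein.normal_overweight
      when: {phenotype: [normal_weight, overweight]}
      method: per_kg
      g_per_kg: 1.2
      basis: current_weight
      provenance: published
      description: normal/overweight, 1.2 g/kg current weight
    - id: protein.obese
      when: {phenotype: [obesity_1, obesity_2]}
      method: per_kg
      g_per_kg: 1.2
      basis: ideal_bmi
      provenance: assumption
      description: obese, 1.2 g/kg of the 25-BMI ideal weight

carbohydrate:
  share_min: 45          # % of energy
  share_max: 50
  pco2_threshold_mmhg: 50
  pco2_shift_points: 5   # percentage points moved from carbohydrate to fat when pCO2 > threshold
  shift_provenance: assumption

sugar:
  default_max_share: 15  # % of energy
  t2dm_max_share: 10

saturated_fat:
  max_share: 10          # % of energy

cholesterol:
  default_max_mg: 300
  hypercholesterolemia_max_mg: 200

sodium:
  max_mg: 2000

calcium:
  mg: 1200
  provenance: assumption  # "slightly higher than LARN" — LARN adults 1000 mg/day

fiber:
  min_g: 15
  max_g: 25
  provenance: assumption  # "lower than LARN" — LARN suggests ~25-30 g/day

supplements:
  rules:
    - id: supplement.cachectic
      when: {cachectic: true}
      bcaa: true
      energy_protein: true
      provenance: published
      description: cachexia always gets BCAA and energy-protein supplementation
    - id: supplement.sarcopenic.lean
      when: {sarcopenic: true, phenotype: [underweight, normal_weight]}
      bcaa: true
      energy_protein: true
      provenance: published
      description: sarcopenic underweight/normal-weight get both supplements
    - id: supplement.sarcopenic
      when: {sarcopenic: true}
      bcaa: true
      energy_protein: false
      provenance: published
      description: any other sarcopenic phenotype gets BCAA only
    - id: supplement.default
      when: {}
      bcaa: false
      energy_protein: false
      provenance: published
      description: no supplementation by default

meals:
  per_day: 5
  provenance: assumption  # "small and frequent meals", count not specified
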