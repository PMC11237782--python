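# nutricopd

Deterministic, explainable nutritional decision support for patients with
chronic obstructive pulmonary disease (COPD).

Nutrition strongly modulates the course of COPD — malnutrition, sarcopenia
and cachexia are common and prognostically important — yet pulmonary
rehabilitation programs often lack dietetic resources. `nutricopd` encodes
the screening and recommendation logic a clinical nutrition team would
apply, as a transparent rule engine: from one routine assessment it infers
the patient's nutritional phenotype and derives a complete, tailored
dietary prescription, with every output value traceable to the rule that
produced it. It is aimed at clinical-informatics researchers and
decision-support developers who need reproducible, auditable inference
rather than a black box.

## What it computes

From demographics, anthropometry, spirometry, hand grip, gait speed,
bioimpedance, biochemistry (albumin, CRP, transferrin), an optional blood
gas and comorbidity flags:

**Classification**
- anthropometric phenotype (WHO BMI bands, underweight → obesity III)
- COPD stage I–IV from FEV1 % predicted (≥80 / ≥50 / ≥30 / <30)
- nutritional risk index `NRI = 1.519·albumin(g/L) + 41.7·(current/usual
  weight)`, banded into absence / mild / moderate / severe risk
- sarcopenia ladder (probable / diagnosed / severe) from grip strength,
  appendicular skeletal muscle mass (Sergi bioimpedance equation
  `ASMM = −3.964 + 0.227·RI + 0.095·kg + 1.384·male + 0.064·Xc`,
  `RI = height(cm)²/resistance`) and gait speed
- cachexia: sarcopenia + CRP > 10 mg/L + transferrin < 150 mg/dL +
  albumin < 3.5 g/dL

**Recommendation (14 items)** — basal metabolic rate (Harris-Benedict or
Mifflin-St Jeor by phenotype), total energy (BMR × 1.5 for stage I/II,
× 1.8 for stage III/IV or cachexia), meal frequency, two supplement flags
(BCAA, energy-protein), protein (1.2 g/kg, 1.5 g/kg if sarcopenic, fixed
25% share if cachectic), carbohydrate 45–50% (40–45% when pCO2 > 50 mm Hg),
fat as the conserving remainder, sugar ≤ 15% (10% with type 2 diabetes),
saturated fat ≤ 10%, cholesterol ≤ 300 mg (200 with hypercholesterolemia),
fiber 15–25 g, sodium ≤ 2000 mg, calcium 1200 mg.

Every constant lives in an editable YAML rule table
(`src/nutricopd/data/rules.yaml`) tagged `published` or `assumption`, and
the returned `RuleTrace` maps each output field to the rules that set it.
See `docs/methods.md` for the full model description and the reasoning
behind every assumption-tagged value.

## Worked example

```python
import nutricopd as nc

patient = nc.validate_patient({
    "id": "walkthrough", "gender": "male", "age": 64,
    "current_weight": 70, "usual_weight": 70, "height": 1.75,
    "fev1_percent": 65, "hand_grip": 40, "gait_speed": 1.2,
    "resistance": 500, "reactance": 50,
    "albumin": 4.0, "crp": 2.0, "transferrin": 250,
})
classification, recommendation, trace = nc.recommend(patient)
```

Running `python examples/recommendation_walkthrough.py` prints:

```
classification:
  phenotype        normal_weight  (BMI 22.86 kg/m²)
  COPD stage       II
  NRI              102.46 → absence risk
  ASMM             21.17 kg  (RI 61.25 cm²/Ω)
  sarcopenia       none   cachectic: False
recommendation:
  BMR              1470 kcal/day
  total energy     2205 kcal/day  (factor 1.5)
  protein          84 g  (15.2% of energy)
  carbohydrate     45-50%  (248-276 g)
  fat              34.8-39.8%  (85-97 g)
  sugar ≤          15%  (83 g)
  saturated fat ≤  10%  (24 g)
  cholesterol ≤    300 mg, sodium ≤ 2000 mg, calcium 1200 mg
  fiber            15-25 g
  meals/day        5, BCAA: False, energy-protein suppl.: False
```

Reading: a 70 kg, 1.75 m, 64-year-old man with moderate COPD gets a
Harris-Benedict BMR of 1470 kcal, scaled by the stage-I/II factor 1.5 to a
2205 kcal/day target; protein at 1.2 g/kg gives 84 g (~15% of energy), the
carbohydrate band is 45–50% and fat takes the remainder so the shares sum
to 100% at both band ends. His NRI above 100 means no nutritional risk,
and with normal grip strength the sarcopenia/cachexia rules stay silent.

Other example scripts: `cachexia_dominance.py` (cachexia forcing the 1.8
factor, 25% protein share and both supplements), `synthetic_cohort.py`
(archetype and seeded random cohorts), `triple_export.py` (RDF/Turtle
export in the `copd:` vocabulary), `agreement_summary.py` (expert-panel
validation statistics).

A thin CLI wraps the same functions:

```bash
nutricopd cohort --n 100 --seed 1 --out cohort.csv
nutricopd classify --input cohort.csv
nutricopd report --input cohort.csv --format markdown
nutricopd export-ttl --input cohort.csv
```

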