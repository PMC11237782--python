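# Methods

`nutricopd` is a deterministic rule engine for nutritional decision support
in chronic obstructive pulmonary disease (COPD). It reproduces, as plain
auditable code, the inference pipeline of an ontology-based clinical
decision support system: classify the patient, compute their energy
requirement, then apply a nutrient rule base to emit a 14-item dietary
recommendation with per-field rule provenance. There is no learning and no
stochastic component in the inference path; identical inputs always produce
identical outputs.

## Classification model

A patient record carries demographics, anthropometry, spirometry,
functional tests, bioimpedance, biochemistry, an optional blood gas and two
comorbidity flags. Five labels are inferred:

**Anthropometric phenotype** — the WHO BMI bands, normalized to half-open
intervals `[lo, hi)` so the mapping is total (no gap between 24.9 and
25.0): underweight < 18.5, normal [18.5, 25), overweight [25, 30),
obesity I [30, 35), obesity II [35, 40), obesity III ≥ 40. The nutrient
rule base defines five phenotype branches; a BMI ≥ 40 is labelled obesity
III but routed to the obesity-II branch with a logged warning.

**COPD stage** — FEV1 % predicted: ≥ 80 stage I, [50, 80) II, [30, 50) III,
< 30 IV. Diagnosing COPD itself (FEV1/FVC gating) is assumed done upstream.

**Nutritional risk index** — `NRI = 1.519·albumin(g/L) + 41.7·(current /
usual weight)`. Albumin is measured in g/dL and converted to g/L before the
coefficient, which is what makes the 3.5 g/dL cachexia cutoff and the
≈100-point risk scale mutually consistent. Risk bands: > 100 absence,
[97.5, 100] mild (closed at 100), [83.5, 97.5) moderate, < 83.5 severe.
When the usual weight is unknown it defaults to the current weight
(neutral ratio 1).

**Sarcopenia ladder** — three criteria: (1) low strength, hand grip
< 27 kg (men) / < 16 kg (women); (2) low muscle quantity, appendicular
skeletal muscle mass (ASMM) < 20 kg / < 15 kg **or** ASMM/height² <
7 / 5.5 kg/m² (the two sub-conditions are alternatives — either one
indicates low quantity, per the EWGSOP-style operational definition);
(3) poor performance, gait speed ≤ 0.8 m/s. Criterion 1 alone → probable;
1+2 → diagnosed; all three → severe. ASMM is estimated with the Sergi
bioimpedance equation `ASMM = −3.964 + 0.227·RI + 0.095·kg + 1.384·male +
0.064·Xc` on the resistive index `RI = height(cm)²/resistance`.

**Cachexia** — sarcopenia (any level) plus the inflammatory/biochemical
triad, all strict: CRP > 10 mg/L, transferrin < 150 mg/dL, albumin
< 3.5 g/dL. Cachexia therefore implies sarcopenia by construction, and the
classification type refuses to represent the contrary.

## Energy model

The basal metabolic rate (BMR) equation is selected by phenotype:
Harris-Benedict for underweight/normal weight, Mifflin-St Jeor for
overweight and obese patients. The male Harris-Benedict constants are the
ones the deployed rule base prints (66.5 + 13.75·kg + 5·cm − 6.78·years);
the female Harris-Benedict (655.1 + 9.563·kg + 1.850·cm − 4.676·years) and
both Mifflin forms (10·kg + 6.25·cm − 5·years + 5 / − 161) use the standard
published constants of the cited equations.

The BMR is rounded to an integer, then multiplied by the correction factor
and rounded again — two chained roundings, exactly as the deployed
inference rules chain them. Rounding is half-away-from-zero (the SWRL
`round` built-in convention); the tie-break is an implementation choice,
as ties are only reachable on `.5` products of the 1.5 factor. The factor
is 1.5 for stage I/II and 1.8 for stage III/IV, sarcopenic or not; cachexia
always forces 1.8 regardless of phenotype and stage. Physical activity
level is deliberately not an input (its impact was considered marginal in
this population); passing one to `total_energy` only logs an advisory.

## Nutrient rule base

All clinical constants and the decision tables live in
`src/nutricopd/data/rules.yaml`, one row per rule with a stable id and a
provenance tag (`published` for values taken from the encoded guideline
rule base, `assumption` for values this implementation had to fix where
the source gives a direction but no number). The engine validates the
table at load time: over the full lattice of reachable classifications
(5 phenotype branches × 4 stages × 4 sarcopenia levels × cachexia), every
decision section must match exactly one row — no gaps, and first-match
ordering precludes conflicts.

Protein: cachectic patients get a fixed 25% energy share (grams derived at
4 kcal/g). Everyone else gets grams per kg of a phenotype-dependent basis
weight — current weight for normal/overweight, the weight at a reference
BMI of 22.5 kg/m² for underweight (the target is raised to fight the
underweight state), and the ideal weight at BMI 25 for obese branches —
at 1.2 g/kg, raised to 1.5 g/kg for sarcopenic non-cachectic patients.
The 1.5 multiplier, and its application to the same basis-weight rules,
are `assumption` rows: the source states that recommendations vary by real
or ideal weight or BMI without printing the sarcopenic multiplier, and
1.5 g/kg is the conventional clinical choice for muscle-mass preservation.

Shares: carbohydrate 45–50% of energy; when pCO2 > 50 mm Hg the band
shifts 5 percentage points toward fat (40–45%) to lower the respiratory
quotient — the direction is published, the 5-point magnitude is an
assumption. Fat takes the remainder, so protein + carb_max + fat_min =
protein + carb_min + fat_max = 100 by construction. Sugar ≤ 15% (10% under
type 2 diabetes), saturated fat ≤ 10%, cholesterol ≤ 300 mg/day (200 under
hypercholesterolemia), sodium ≤ 2000 mg/day. Fiber 15–25 g/day and calcium
1200 mg/day are `assumption` values chosen to satisfy the stated direction
relative to the Italian LARN reference intakes (fiber lower, calcium
slightly higher). Meals are fractioned; the count (5/day) is an assumption
("small and frequent" with no number). An absent pCO2 is treated as
≤ 50 mm Hg. If a protein share ever exceeded what the carbohydrate band
leaves for fat, the engine raises an infeasible-share error rather than
emit a non-conserving recommendation.

Supplements: cachexia → BCAA and energy-protein supplementation, always;
sarcopenic underweight/normal-weight → both; any other sarcopenic
phenotype → BCAA only. The grammatically ambiguous source sentence is read
as requiring sarcopenia for the normal-weight case.

## Explainability

Every classification and recommendation field is covered by at least one
entry of the returned `RuleTrace` (rule id, description, affected fields,
provenance). Reports annotate each value with its rules and provenance, so
a reader can distinguish guideline-sourced numbers from implementation
assumptions at a glance; assumption-provenance rules are additionally
logged at info level, fired rules at debug level.

## Synthetic data

The package generates all of its own test inputs; no real patient data is
included or required.

*Archetypes* invert the cutoff tables constructively: for each of the 672
reachable label combinations (6 phenotypes × 4 stages × 4 NRI classes ×
7 sarcopenia/cachexia statuses), representative in-band values are chosen
(BMI 17/22/27/32/37/42, FEV1 90/65/40/25, NRI targets 102/98.75/90/75) and
the remaining inputs are solved for — albumin/weight-ratio from the NRI
formula, bioimpedance resistance from the inverted Sergi equation to hit
an ASMM 2–3 kg beyond the relevant cutoff. Round-tripping (requested
labels = classified labels) holds for every archetype and is asserted in
the tests.

*Boundary cases* place paired patients at each published cutoff and one
display decimal below it (0.1 for FEV1, BMI, grip and ASMM; 0.01 for gait
speed), verifying strict-vs-inclusive comparisons at printed precision.

*Random cohorts* draw from fixed plausible ranges for an elderly pulmonary
rehabilitation population (age 40–90, BMI 14–42 kg/m², FEV1 15–110%, grip
5–50 kg, gait 0.3–1.5 m/s, resistance 350–800 Ω, albumin 2.5–5 g/dL, …)
with a seeded NumPy generator; same spec → identical cohort. The ranges
make cohorts clinically sensible; they do not model a real population's
joint distribution, so prevalence-like summaries over random cohorts
(e.g. how often cachexia occurs) carry no epidemiological meaning.
Passing tests demonstrate the rule logic is correct on every reachable
path, not that the recommendations are clinically optimal for any
particular population.

## Validation statistics

`summarize_agreement` reproduces the published expert-panel statistics
from the raw Likert scores: per-item mean and sample (n−1) standard
deviation, rounded half-up to two decimals, plus the mean and sample SD
of the item means. On the packaged seven-rater, five-profile agreement
table this yields FG = 3.29 (1.38) and an overall mean of 4.23. The
overall SD computes to 0.53 from the printed scores (the originally
reported 0.52 is not derivable from them under any standard SD
convention; the function reports what the scores give). For the
acceptability questionnaire, the function computes each subscale from its
own scores, which assigns 4.86 to the two perceived-usefulness rows and
4.14 to intention-to-use.

## Problem sizes and numerics

The lattice sweeps used throughout the tests and the acceptance script
cover all 672 archetypes plus a 300-patient random cohort; the
partition-totality check compares the interval maps against independent
nested-conditional oracles on 10⁵ random inputs. All comparisons on
derived floats use explicit tolerances (0.01 percentage points for share
conservation, 0.5 g for gram conversions); cutoff comparisons themselves
are exact, matching the strict/inclusive inequalities of the published
tables. Degenerate inputs (zero weight/height/resistance, non-positive
FEV1, heights over 3 m that are probably centimetres) are rejected at
validation with the offending field named.

## Known limitations

- The engine encodes the Italian guideline context its rule base came
  from; other national references require editing `rules.yaml`.
- Obesity degree III has no dedicated rule branch and reuses obesity II.
- Single-assessment only: no longitudinal trends, medications, free-text
  notes or indirect calorimetry.
- The triple export mirrors the `copd:` vocabulary for interoperability
  experiments; it is not a full OWL ontology and performs no DL reasoning
  (the deterministic rule engine replaces it by design).
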