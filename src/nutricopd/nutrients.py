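"""The nutrient rule base: from classification + corrected energy to the
14-item recommendation.

The decision tables (protein, supplements, correction factors) and every
numeric cap live in the editable rule table; this module interprets them,
derives the macronutrient shares and gram amounts, and assembles the
complete recommendation with a per-field rule trace.

Macronutrient logic: protein is set in grams (1.2 g/kg of a
phenotype-dependent basis weight; 1.5 g/kg when sarcopenic) except for
cachectic patients, who get a fixed 25% energy share; carbohydrate is a
45-50% band (shifted to 40-45% when pCO2 > 50 mm Hg to favour lipids,
which load the respiratory quotient less); fat takes the remainder, so the
three shares conserve 100% at both ends of the carbohydrate band.
"""

from __future__ import annotations

import logging
from typing import Optional

from .energy import total_energy
from .model import (
    KCAL_PER_G,
    NutritionalRecommendation,
    PatientClassification,
    PatientInput,
    Phenotype,
    Provenance,
    RuleTrace,
    SarcopeniaLevel,
)
from .rules import RuleBase, default_rules, rule_phenotype

logger = logging.getLogger(__name__)


class InfeasibleShareError(ValueError):
    """The fired share rules cannot sum to 100% of energy."""


def _ctx(classification: PatientClassification) -> dict:
    return {
        "phenotype": rule_phenotype(classification.phenotype).value,
        "stage": classification.copd_stage.value,
        "sarcopenic": classification.sarcopenia_level is not SarcopeniaLevel.none,
        "sarcopenia_level": classification.sarcopenia_level.value,
        "cachectic": classification.cachectic,
    }


def protein_basis_weight(basis: str, current_weight: float, height: float,
                         rules: RuleBase) -> float:
    """Weight (kg) a per-kg protein rule applies to."""
    if basis == "current_weight":
        return current_weight
    if basis == "reference_bmi":
        return rules.section("protein", "reference_bmi") * height**2
    if basis == "ideal_bmi":
        return rules.section("protein", "ideal_bmi") * height**2
    raise ValueError(f"unknown protein basis {basis!r}")


def protein_targets(classification: PatientClassification, energy_kcal: int,
                    current_weight: float, height: float,
                    rules: Optional[RuleBase] = None
                    ) -> tuple[float, float, dict]:
    """Daily protein in grams and as % of energy, plus the fired rule row.

    Non-cachectic rules fix grams (g/kg of the basis weight) and derive the
    share at 4 kcal/g; the cachectic rule fixes the share at 25% and
    derives grams.
    """
    if energy_kcal <= 0:
        raise InfeasibleShareError("energy must be positive to derive protein share")
    rules = rules or default_rules()
    row = rules.match_protein(_ctx(classification))
    if row["method"] == "fixed_share":
        share = float(rules.section("protein", "cachectic_share"))
        grams = share / 100.0 * energy_kcal / KCAL_PER_G["protein"]
    else:
        basis_kg = protein_basis_weight(row["basis"], current_weight, height, rules)
        grams = float(row["g_per_kg"]) * basis_kg
        share = grams * KCAL_PER_G["protein"] / energy_kcal * 100.0
    return grams, share, dict(row)


def energy_shares(protein_share: float, pco2: Optional[float], has_t2dm: bool,
                  rules: Optional[RuleBase] = None) -> dict:
    """Carbohydrate band, fat remainder, sugar and saturated-fat caps (% energy).

    An absent pCO2 is treated as ≤ 50 mm Hg (no lipid boost). Raises
    :class:`InfeasibleShareError` if the protein share leaves no room for
    fat at the top of the carbohydrate band.
    """
    rules = rules or default_rules()
    carb = rules.section("carbohydrate")
    carb_min, carb_max = float(carb["share_min"]), float(carb["share_max"])
    lipid_boost = pco2 is not None and pco2 > carb["pco2_threshold_mmhg"]
    if lipid_boost:
        shift = float(carb["pco2_shift_points"])
        carb_min, carb_max = carb_min - shift, carb_max - shift
    fat_min = 100.0 - protein_share - carb_max
    fat_max = 100.0 - protein_share - carb_min
    if fat_min < 0:
        raise InfeasibleShareError(
            f"protein share {protein_share:.1f}% plus carbohydrate up to "
            f"{carb_max:.0f}% exceeds 100% of energy")
    sugar = rules.section("sugar")
    sugar_max = float(sugar["t2dm_max_share"] if has_t2dm else sugar["default_max_share"])
    satfat_max = float(rules.section("saturated_fat", "max_share"))
    return {
        "carb_share_min": carb_min,
        "carb_share_max": carb_max,
        "fat_share_min": fat_min,
        "fat_share_max": fat_max,
        "sugar_share_max": sugar_max,
        "satfat_share_max": satfat_max,
        "lipid_boost": lipid_boost,
        "t2dm": has_t2dm,
    }


def micronutrient_caps(has_hypercholesterolemia: bool,
                       rules: Optional[RuleBase] = None) -> dict:
    """Cholesterol, sodium, calcium and fiber targets."""
    rules = rules or default_rules()
    chol = rules.section("cholesterol")
    return {
        "cholesterol_max_mg": float(
            chol["hypercholesterolemia_max_mg"] if has_hypercholesterolemia
            else chol["default_max_mg"]),
        "sodium_max_mg": float(rules.section("sodium", "max_mg")),
        "calcium_mg": float(rules.section("calcium", "mg")),
        "fiber_min_g": float(rules.section("fiber", "min_g")),
        "fiber_max_g": float(rules.section("fiber", "max_g")),
    }


def supplementation_flags(classification: PatientClassification,
                          rules: Optional[RuleBase] = None
                          ) -> tuple[bool, bool, dict]:
    """(bcaa, energy_protein) supplement flags plus the fired rule row."""
    rules = rules or default_rules()
    row = rules.match_supplements(_ctx(classification))
    return bool(row["bcaa"]), bool(row["energy_protein"]), dict(row)


def assemble_recommendation(classification: PatientClassification,
                            p: PatientInput,
                            rules: Optional[RuleBase] = None
                            ) -> tuple[NutritionalRecommendation, RuleTrace]:
    """Run energy and all nutrient rules; return the 14-item block + trace."""
    rules = rules or default_rules()
    if classification.phenotype is Phenotype.obesity_3:
        logger.warning(
            "patient %s: obesity degree III routed to the obesity-II rule branch",
            p.id)
    trace = RuleTrace()

    bmr, energy, factor, equation, factor_row = total_energy(
        p.gender, p.age, p.current_weight, p.height,
        classification.phenotype, classification.copd_stage,
        classification.sarcopenia_level, classification.cachectic, rules)
    trace = trace.add("energy.bmr." + equation.value,
                      f"BMR via {equation.value.replace('_', '-')} equation",
                      ["bmr_kcal"])
    trace = trace.add(factor_row["id"], factor_row["description"],
                      ["energy_kcal"], factor_row.get("provenance", "published"))

    grams, share, protein_row = protein_targets(
        classification, energy, p.current_weight, p.height, rules)
    trace = trace.add(protein_row["id"], protein_row["description"],
                      ["protein_g", "protein_share"],
                      protein_row.get("provenance", "published"))

    shares = energy_shares(share, p.pco2, p.has_t2dm, rules)
    carb_id = "carb.lipid_boost" if shares["lipid_boost"] else "carb.base_band"
    carb_desc = ("carbohydrate band shifted 5 points to fat for pCO2 > 50 mm Hg"
                 if shares["lipid_boost"] else "carbohydrate 45-50% of energy")
    carb_prov = (rules.section("carbohydrate")["shift_provenance"]
                 if shares["lipid_boost"] else "published")
    trace = trace.add(carb_id, carb_desc,
                      ["carb_share_min", "carb_share_max", "carb_g_min", "carb_g_max"],
                      carb_prov)
    trace = trace.add("fat.remainder",
                      "fat takes the remainder so shares conserve 100%",
                      ["fat_share_min", "fat_share_max", "fat_g_min", "fat_g_max"])
    trace = trace.add("sugar.t2dm_cap" if shares["t2dm"] else "sugar.default_cap",
                      "sugar ≤ 10% of energy under type 2 diabetes"
                      if shares["t2dm"] else "sugar ≤ 15% of energy",
                      ["sugar_share_max", "sugar_g_max"])
    trace = trace.add("satfat.cap", "saturated fat ≤ 10% of energy",
                      ["satfat_share_max", "satfat_g_max"])

    caps = micronutrient_caps(p.has_hypercholesterolemia, rules)
    trace = trace.add(
        "cholesterol.hyperchol_cap" if p.has_hypercholesterolemia else "cholesterol.cap",
        "cholesterol ≤ 200 mg/day under hypercholesterolemia"
        if p.has_hypercholesterolemia else "cholesterol ≤ 300 mg/day",
        ["cholesterol_max_mg"])
    trace = trace.add("sodium.cap", "sodium ≤ 2000 mg/day", ["sodium_max_mg"])
    trace = trace.add("calcium.target", "calcium 1200 mg/day, slightly above LARN",
                      ["calcium_mg"], rules.section("calcium", "provenance"))
    trace = trace.add("fiber.band", "fiber 15-25 g/day, below LARN to spare appetite",
                      ["fiber_min_g", "fiber_max_g"], rules.section("fiber", "provenance"))

    bcaa, energy_protein, supp_row = supplementation_flags(classification, rules)
    trace = trace.add(supp_row["id"], supp_row["description"],
                      ["bcaa_supplement", "energy_protein_supplement"],
                      supp_row.get("provenance", "published"))

    meals = int(rules.section("meals", "per_day"))
    trace = trace.add("meals.fractioned", "small and frequent meals",
                      ["meals_per_day"], rules.section("meals", "provenance"))

    def g(share_pct: float, kcal_per_g: float) -> float:
        return share_pct / 100.0 * energy / kcal_per_g

    rec = NutritionalRecommendation(
        bmr_kcal=bmr,
        energy_kcal=energy,
        meals_per_day=meals,
        energy_protein_supplement=energy_protein,
        bcaa_supplement=bcaa,
        protein_share=share,
        protein_g=grams,
        carb_share_min=shares["carb_share_min"],
        carb_share_max=shares["carb_share_max"],
        carb_g_min=g(shares["carb_share_min"], KCAL_PER_G["carbohydrate"]),
        carb_g_max=g(shares["carb_share_max"], KCAL_PER_G["carbohydrate"]),
        fat_share_min=shares["fat_share_min"],
        fat_share_max=shares["fat_share_max"],
        fat_g_min=g(shares["fat_share_min"], KCAL_PER_G["fat"]),
        fat_g_max=g(shares["fat_share_max"], KCAL_PER_G["fat"]),
        sugar_share_max=shares["sugar_share_max"],
        sugar_g_max=g(shares["sugar_share_max"], KCAL_PER_G["carbohydrate"]),
        satfat_share_max=shares["satfat_share_max"],
        satfat_g_max=g(shares["satfat_share_max"], KCAL_PER_G["fat"]),
        **caps,
    )
    for assumption in (e for e in trace.entries if e.provenance is Provenance.assumption):
        logger.info("assumption-provenance rule fired: %s (%s)",
                    assumption.rule_id, ", ".join(assumption.fields))
    return rec, trace


def recommend(p: PatientInput, rules: Optional[RuleBase] = None
              ) -> tuple[PatientClassification, NutritionalRecommendation, RuleTrace]:
    """Classify a patient and assemble their recommendation in one call.

    The returned trace concatenates the classification and recommendation
    traces, so every emitted field of both blocks is covered.
    """
    from .classify import classify_patient

    rules = rules or default_rules()
    classification, ctrace = classify_patient(p, rules)
    rec, rtrace = assemble_recommendation(classification, p, rules)
    return classification, rec, RuleTrace(entries=ctrace.entries + rtrace.entries)
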