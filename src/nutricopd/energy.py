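"""Basal metabolic rate and corrected total daily energy requirement.

The predictive equation is chosen by anthropometric phenotype:
Harris-Benedict for underweight/normal-weight patients, Mifflin-St Jeor
for overweight/obese ones. The BMR is rounded to an integer first, then
multiplied by a stage/cachexia correction factor (1.5 for stage I/II,
1.8 for stage III/IV or any cachectic patient) and rounded again — the two
roundings chain exactly as the deployed inference rules do. Physical
activity level is deliberately not an input; supplying one only logs an
advisory (its impact was considered marginal in this population).
"""

from __future__ import annotations

import enum
import logging
import math
from typing import Optional

from .model import CopdStage, Gender, Phenotype, SarcopeniaLevel
from .rules import RuleBase, default_rules, rule_phenotype

logger = logging.getLogger(__name__)


class BmrEquation(str, enum.Enum):
    harris_benedict = "harris_benedict"
    mifflin = "mifflin"


def round_half_away(x: float) -> int:
    """Round half away from zero (the SWRL ``round`` built-in convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_bmr_equation(phenotype: Phenotype) -> BmrEquation:
    """Harris-Benedict for underweight/normal weight, Mifflin otherwise."""
    if rule_phenotype(phenotype) in (Phenotype.underweight, Phenotype.normal_weight):
        return BmrEquation.harris_benedict
    return BmrEquation.mifflin


def compute_bmr(gender: Gender, age: int, weight: float, height: float,
                equation: BmrEquation, rules: Optional[RuleBase] = None) -> int:
    """BMR in kcal/day, rounded to an integer.

    Harris-Benedict (male): 66.5 + 13.75·kg + 5·cm − 6.78·years.
    Harris-Benedict (female): 655.1 + 9.563·kg + 1.850·cm − 4.676·years.
    Mifflin-St Jeor: 10·kg + 6.25·cm − 5·years + 5 (male) / − 161 (female).
    """
    if weight <= 0 or height <= 0 or age <= 0:
        raise ValueError("age, weight and height must be positive")
    c = (rules or default_rules()).constants["bmr"]
    cm = height * 100.0
    if equation is BmrEquation.harris_benedict:
        k = c["harris_benedict"][gender.value]
        raw = k["intercept"] + k["weight"] * weight + k["height_cm"] * cm - k["age"] * age
    else:
        k = c["mifflin"]
        offset = k["male_offset"] if gender is Gender.male else k["female_offset"]
        raw = k["weight"] * weight + k["height_cm"] * cm - k["age"] * age + offset
    return round_half_away(raw)


def correction_factor(stage: CopdStage, sarcopenia_level: SarcopeniaLevel,
                      cachectic: bool, rules: Optional[RuleBase] = None
                      ) -> tuple[float, dict]:
    """Stage/cachexia correction factor and the rule row that fired.

    Cachexia always forces 1.8; otherwise stage I/II → 1.5 and
    stage III/IV → 1.8, sarcopenic or not.
    """
    rules = rules or default_rules()
    ctx = {
        "phenotype": None,
        "stage": stage.value,
        "sarcopenic": sarcopenia_level is not SarcopeniaLevel.none,
        "sarcopenia_level": sarcopenia_level.value,
        "cachectic": cachectic,
    }
    row = rules.match_factor(ctx)
    return float(row["factor"]), dict(row)


def corrected_energy(bmr_kcal: int, factor: float) -> int:
    """Total daily energy: the already-rounded BMR times the factor, rounded."""
    if bmr_kcal <= 0:
        raise ValueError("bmr_kcal must be positive")
    return round_half_away(bmr_kcal * factor)


def total_energy(gender: Gender, age: int, weight: float, height: float,
                 phenotype: Phenotype, stage: CopdStage,
                 sarcopenia_level: SarcopeniaLevel, cachectic: bool,
                 rules: Optional[RuleBase] = None,
                 physical_activity_level: Optional[float] = None
                 ) -> tuple[int, int, float, BmrEquation, dict]:
    """Convenience pipeline: (bmr, energy, factor, equation, factor rule row)."""
    if physical_activity_level is not None:
        logger.info(
            "physical activity level %.2f supplied but not used: the correction "
            "factor is defined by COPD stage and cachexia only",
            physical_activity_level)
    rules = rules or default_rules()
    equation = select_bmr_equation(phenotype)
    bmr = compute_bmr(gender, age, weight, height, equation, rules)
    factor, row = correction_factor(stage, sarcopenia_level, cachectic, rules)
    return bmr, corrected_energy(bmr, factor), factor, equation, row
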