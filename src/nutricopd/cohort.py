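"""Synthetic patient generation.

Three generators, all free of external data:

* :func:`make_archetype` / :func:`generate_archetypes` — constructive
  inversion of the cutoff tables: pick input values that land inside each
  requested (phenotype, stage, NRI class, sarcopenia level, cachexia)
  region, so every rule path is reachable and round-trip testable
  (requested labels == classified labels).
* :func:`generate_boundary_cases` — paired patients at each published
  cutoff and one display decimal below/above it.
* :func:`generate_cohort` — seeded random patients drawn from fixed
  plausible clinical ranges (not a population model).
"""

from __future__ import annotations

import enum
import itertools
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .model import (
    CopdStage,
    Gender,
    NriClass,
    PatientInput,
    Phenotype,
    SarcopeniaLevel,
    validate_patient,
)
from .rules import RuleBase, default_rules


class CohortError(ValueError):
    pass


class Coverage(str, enum.Enum):
    lattice = "lattice"
    boundary = "boundary"
    random = "random"


class CohortSpec(BaseModel):
    """Parameters for synthetic cohort generation."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(gt=0)
    seed: int = Field(ge=0)
    coverage: Coverage = Coverage.random


#: Representative BMI (kg/m²) inside each phenotype band.
_BMI_TARGET = {
    Phenotype.underweight: 17.0,
    Phenotype.normal_weight: 22.0,
    Phenotype.overweight: 27.0,
    Phenotype.obesity_1: 32.0,
    Phenotype.obesity_2: 37.0,
    Phenotype.obesity_3: 42.0,
}

#: Representative FEV1 % predicted inside each stage band.
_FEV1_TARGET = {
    CopdStage.I: 90.0,
    CopdStage.II: 65.0,
    CopdStage.III: 40.0,
    CopdStage.IV: 25.0,
}

#: Target NRI value inside each risk band.
_NRI_TARGET = {
    NriClass.absence: 102.0,
    NriClass.mild: 98.75,
    NriClass.moderate: 90.0,
    NriClass.severe: 75.0,
}

#: Ranges the random generator draws from; chosen to be clinically sensible
#: for an elderly COPD rehabilitation population, not to model one.
PLAUSIBLE_RANGES = {
    "age": (40, 90),            # years
    "height": (1.50, 1.90),     # m
    "bmi": (14.0, 42.0),        # kg/m² → weight = bmi·height²
    "weight_ratio": (0.75, 1.25),  # current/usual
    "fev1_percent": (15.0, 110.0),
    "hand_grip": (5.0, 50.0),   # kg
    "gait_speed": (0.3, 1.5),   # m/s
    "resistance": (350.0, 800.0),  # Ω
    "reactance": (20.0, 70.0),  # Ω
    "albumin": (2.5, 5.0),      # g/dL
    "crp": (0.0, 30.0),         # mg/L
    "transferrin": (100.0, 350.0),  # mg/dL
    "pco2": (30.0, 60.0),       # mm Hg, present for half the patients
}


def _solve_resistance_for_asmm(asmm_target: float, weight: float, height: float,
                               gender: Gender, reactance: float,
                               rules: RuleBase) -> float:
    """Invert the Sergi equation: resistance giving the target ASMM."""
    c = rules.constants["asmm"]
    sex = 1.0 if gender is Gender.male else 0.0
    base = (c["intercept"] + c["weight"] * weight + c["male_offset"] * sex
            + c["reactance"] * reactance)
    ri = (asmm_target - base) / c["resistive_index"]
    if ri <= 0:
        raise CohortError(
            f"ASMM target {asmm_target:.1f} kg unreachable at weight {weight:.1f} kg")
    return (height * 100.0) ** 2 / ri


def _sarcopenia_inputs(level: SarcopeniaLevel, gender: Gender, weight: float,
                       height: float, reactance: float, rules: RuleBase
                       ) -> tuple[float, float, float]:
    """(hand_grip, gait_speed, resistance) landing in the requested level."""
    cut = rules.cutoffs["sarcopenia"]
    sex = gender.value
    grip_cut = cut["hand_grip_kg"][sex]
    asmm_cut = cut["asmm_kg"][sex]
    ratio_cut = cut["asmm_over_height2"][sex]
    asmm_low = min(asmm_cut, ratio_cut * height**2) - 3.0
    asmm_high = max(asmm_cut, ratio_cut * height**2) + 2.0
    if level is SarcopeniaLevel.none:
        grip, asmm_target, gait = grip_cut + 13.0, asmm_high, 1.2
    elif level is SarcopeniaLevel.probable:
        grip, asmm_target, gait = grip_cut - 7.0, asmm_high, 1.2
    elif level is SarcopeniaLevel.diagnosed:
        grip, asmm_target, gait = grip_cut - 7.0, asmm_low, 1.0
    else:
        grip, asmm_target, gait = grip_cut - 7.0, asmm_low, 0.5
    resistance = _solve_resistance_for_asmm(
        asmm_target, weight, height, gender, reactance, rules)
    return max(grip, 0.0), gait, resistance


def make_archetype(phenotype: Phenotype, stage: CopdStage, nri_class: NriClass,
                   sarcopenia_level: SarcopeniaLevel, cachectic: bool,
                   gender: Gender = Gender.male,
                   patient_id: Optional[str] = None,
                   rules: Optional[RuleBase] = None) -> PatientInput:
    """Build one patient whose classification lands on the requested labels.

    Raises :class:`CohortError` for infeasible requests (cachexia without
    sarcopenia).
    """
    rules = rules or default_rules()
    if cachectic and sarcopenia_level is SarcopeniaLevel.none:
        raise CohortError("cachexia is a particular case of sarcopenia: "
                          "cachectic + sarcopenia 'none' is infeasible")
    height = 1.70
    weight = _BMI_TARGET[phenotype] * height**2
    nri_c = rules.constants["nri"]
    nri_target = _NRI_TARGET[nri_class]
    if cachectic:
        albumin, crp, transferrin = 3.2, 20.0, 100.0
    else:
        # albumin at ratio 1 when that lands in-band, else solve the ratio
        albumin = min(4.5, max(2.0, (nri_target - nri_c["weight_ratio_coeff"])
                               / (nri_c["albumin_g_per_l_coeff"] * 10.0)))
        crp, transferrin = 2.0, 250.0
    ratio = ((nri_target - nri_c["albumin_g_per_l_coeff"] * albumin * 10.0)
             / nri_c["weight_ratio_coeff"])
    if ratio <= 0:
        raise CohortError(f"NRI target {nri_target} unreachable at albumin {albumin}")
    usual_weight = weight / ratio
    reactance = 40.0
    grip, gait, resistance = _sarcopenia_inputs(
        sarcopenia_level, gender, weight, height, reactance, rules)
    label = "cachectic" if cachectic else sarcopenia_level.value
    pid = patient_id or (f"arch-{phenotype.value}-{stage.value}-{nri_class.value}"
                         f"-{sarcopenia_level.value}-{label}-{gender.value}")
    return validate_patient({
        "id": pid,
        "gender": gender.value,
        "age": 65,
        "current_weight": weight,
        "usual_weight": usual_weight,
        "height": height,
        "fev1_percent": _FEV1_TARGET[stage],
        "hand_grip": grip,
        "gait_speed": gait,
        "resistance": resistance,
        "reactance": reactance,
        "albumin": albumin,
        "crp": crp,
        "transferrin": transferrin,
    })


def iter_label_combinations():
    """Every reachable (phenotype, stage, nri_class, level, cachectic) tuple."""
    statuses = [(SarcopeniaLevel.none, False)]
    statuses += [
        (lvl, cach)
        for lvl in (SarcopeniaLevel.probable, SarcopeniaLevel.diagnosed,
                    SarcopeniaLevel.severe)
        for cach in (False, True)
    ]
    for (phenotype, stage, nri_class), (level, cach) in itertools.product(
            itertools.product(Phenotype, CopdStage, NriClass), statuses):
        yield phenotype, stage, nri_class, level, cach


def generate_archetypes(rules: Optional[RuleBase] = None) -> list[PatientInput]:
    """One patient per reachable label combination (gender alternates)."""
    rules = rules or default_rules()
    out = []
    for i, (phenotype, stage, nri_class, level, cach) in enumerate(
            iter_label_combinations()):
        gender = Gender.male if i % 2 == 0 else Gender.female
        out.append(make_archetype(phenotype, stage, nri_class, level, cach,
                                  gender, rules=rules))
    return out


def _boundary_template(gender: Gender, rules: RuleBase) -> dict:
    """A neutral mid-band patient every boundary case is derived from."""
    p = make_archetype(Phenotype.normal_weight, CopdStage.I, NriClass.absence,
                       SarcopeniaLevel.none, False, gender, rules=rules)
    return p.model_dump(mode="json")


def generate_boundary_cases(rules: Optional[RuleBase] = None) -> list[PatientInput]:
    """Paired patients at each published cutoff and one display decimal away.

    Ids encode the varied quantity and its value (``fev1=79.9``) so tests
    can pair them; ε equals the precision the cutoff is printed at (0.1 for
    FEV1/BMI/grip/ASMM, 0.01 for gait speed and NRI-driving albumin).
    """
    rules = rules or default_rules()
    nri_c = rules.constants["nri"]
    out: list[PatientInput] = []

    def emit(base: dict, name: str, value: float, **overrides) -> None:
        rec = dict(base)
        rec.update(overrides)
        rec["id"] = f"bnd-{name}={value:g}"
        out.append(validate_patient(rec))

    male = _boundary_template(Gender.male, rules)
    female = _boundary_template(Gender.female, rules)

    for v in (80.0, 79.9, 50.0, 49.9, 30.0, 29.9):
        emit(male, "fev1", v, fev1_percent=v)
    h = male["height"]
    for bmi in (18.5, 18.4, 25.0, 24.9, 30.0, 29.9, 35.0, 34.9, 40.0, 39.9):
        w = bmi * h**2
        emit(male, "bmi", bmi, current_weight=w, usual_weight=w)
    for nri in (100.1, 100.0, 97.5, 97.4, 83.5, 83.4):
        alb = (nri - nri_c["weight_ratio_coeff"]) / (nri_c["albumin_g_per_l_coeff"] * 10.0)
        emit(male, "nri", nri, albumin=alb, usual_weight=male["current_weight"])
    for v in (27.0, 26.9):
        emit(male, "grip_male", v, hand_grip=v)
    for v in (16.0, 15.9):
        emit(female, "grip_female", v, hand_grip=v)
    # gait only discriminates once grip and muscle-quantity criteria hold
    low_grip, _, low_res = _sarcopenia_inputs(
        SarcopeniaLevel.diagnosed, Gender.male, male["current_weight"], h, 40.0, rules)
    for v in (0.8, 0.81):
        emit(male, "gait", v, gait_speed=v, hand_grip=low_grip, resistance=low_res)
    # absolute ASMM cutoff, at a height where ASMM/h² stays above its cutoff
    for sex, gender, cut, h_abs in (("male", Gender.male, 20.0, 1.60),
                                    ("female", Gender.female, 15.0, 1.55)):
        base = male if gender is Gender.male else female
        w = 22.0 * h_abs**2
        grip_cut = rules.cutoffs["sarcopenia"]["hand_grip_kg"][sex]
        for v in (cut, cut - 0.1):
            # +1e-6 kg at the cutoff keeps the float inversion on the
            # not-below side of the strict < comparison
            target = v + 1e-6 if v == cut else v
            res = _solve_resistance_for_asmm(target, w, h_abs, gender, 40.0, rules)
            emit(base, f"asmm_{sex}", v, height=h_abs, current_weight=w,
                 usual_weight=w, resistance=res, hand_grip=grip_cut - 7.0,
                 gait_speed=1.2)
    # ASMM/height² cutoff, with absolute ASMM above its cutoff (h = 1.75)
    for sex, gender, ratio_cut in (("male", Gender.male, 7.0),
                                   ("female", Gender.female, 5.5)):
        base = male if gender is Gender.male else female
        h_r = 1.75
        w = 22.0 * h_r**2
        grip_cut = rules.cutoffs["sarcopenia"]["hand_grip_kg"][sex]
        for v in (ratio_cut, ratio_cut - 0.1):
            target = (v + 1e-6 if v == ratio_cut else v) * h_r**2
            res = _solve_resistance_for_asmm(target, w, h_r, gender, 40.0, rules)
            emit(base, f"asmm_h2_{sex}", v, height=h_r, current_weight=w,
                 usual_weight=w, resistance=res, hand_grip=grip_cut - 7.0,
                 gait_speed=1.2)
    return out


def generate_cohort(spec: CohortSpec,
                    rules: Optional[RuleBase] = None) -> list[PatientInput]:
    """Generate ``spec.n`` patients, reproducibly from ``spec.seed``."""
    rules = rules or default_rules()
    if spec.coverage is Coverage.lattice:
        pool = generate_archetypes(rules)
    elif spec.coverage is Coverage.boundary:
        pool = generate_boundary_cases(rules)
    else:
        return _random_cohort(spec.n, spec.seed)
    out = []
    for i in range(spec.n):
        p = pool[i % len(pool)]
        out.append(p.model_copy(update={"id": f"{p.id}#{i}"}))
    return out


def _random_cohort(n: int, seed: int) -> list[PatientInput]:
    rng = np.random.default_rng(seed)
    r = PLAUSIBLE_RANGES
    out = []
    for i in range(n):
        height = float(rng.uniform(*r["height"]))
        weight = float(rng.uniform(*r["bmi"])) * height**2
        rec = {
            "id": f"rand-{seed}-{i:05d}",
            "gender": str(rng.choice(["male", "female"])),
            "age": int(rng.integers(r["age"][0], r["age"][1] + 1)),
            "current_weight": weight,
            "usual_weight": weight / float(rng.uniform(*r["weight_ratio"])),
            "height": height,
            "fev1_percent": float(rng.uniform(*r["fev1_percent"])),
            "hand_grip": float(rng.uniform(*r["hand_grip"])),
            "gait_speed": float(rng.uniform(*r["gait_speed"])),
            "resistance": float(rng.uniform(*r["resistance"])),
            "reactance": float(rng.uniform(*r["reactance"])),
            "albumin": float(rng.uniform(*r["albumin"])),
            "crp": float(rng.uniform(*r["crp"])),
            "transferrin": float(rng.uniform(*r["transferrin"])),
            "pco2": float(rng.uniform(*r["pco2"])) if rng.random() < 0.5 else None,
            "has_t2dm": bool(rng.random() < 0.2),
            "has_hypercholesterolemia": bool(rng.random() < 0.2),
        }
        out.append(validate_patient(rec))
    return out
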