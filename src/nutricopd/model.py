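"""Validated domain types shared by every other module.

The engine works on single patient assessments: demographics, anthropometry,
spirometry (FEV1 % predicted), functional tests (hand grip, gait speed),
bioimpedance (resistance, reactance), biochemistry (albumin, C-reactive
protein, transferrin), an optional blood gas (pCO2) and two comorbidity
flags. Everything downstream — anthropometric phenotype, COPD stage,
nutritional risk index, sarcopenia ladder, cachexia, and the 14-item dietary
recommendation — is a deterministic function of one :class:`PatientInput`.
"""

from __future__ import annotations

import enum
from typing import Any, Mapping, Optional, Sequence

import pydantic
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class PatientValidationError(ValueError):
    """Raised when a raw patient record fails validation.

    ``fields`` names the offending input fields so callers (CSV reader, CLI)
    can point at the exact column.
    """

    def __init__(self, message: str, fields: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.fields = tuple(fields)


class Gender(str, enum.Enum):
    male = "male"
    female = "female"


class Phenotype(str, enum.Enum):
    """WHO BMI category, the anthropometric phenotype selecting rule branches."""

    underweight = "underweight"
    normal_weight = "normal_weight"
    overweight = "overweight"
    obesity_1 = "obesity_1"
    obesity_2 = "obesity_2"
    obesity_3 = "obesity_3"


class CopdStage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class NriClass(str, enum.Enum):
    absence = "absence"
    mild = "mild"
    moderate = "moderate"
    severe = "severe"


class SarcopeniaLevel(str, enum.Enum):
    none = "none"
    probable = "probable"
    diagnosed = "diagnosed"
    severe = "severe"


class PatientInput(BaseModel):
    """One patient's raw assessment values.

    Units: weights kg, height m (values > 3 are rejected as probable
    centimetre input), FEV1 % of predicted, grip kg, gait speed m/s,
    bioimpedance ohm, albumin g/dL, CRP mg/L, transferrin mg/dL,
    pCO2 mm Hg. ``usual_weight`` defaults to ``current_weight`` when
    absent (neutral weight-loss ratio of 1).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    gender: Gender
    age: int = Field(gt=0)
    current_weight: float = Field(gt=0)
    usual_weight: float = Field(gt=0)
    height: float = Field(gt=0)
    fev1_percent: float = Field(gt=0)
    hand_grip: float = Field(ge=0)
    gait_speed: float = Field(ge=0)
    resistance: float = Field(gt=0)
    reactance: float = Field(ge=0)
    albumin: float = Field(gt=0)
    crp: float = Field(ge=0)
    transferrin: float = Field(ge=0)
    pco2: Optional[float] = None
    has_t2dm: bool = False
    has_hypercholesterolemia: bool = False

    @model_validator(mode="before")
    @classmethod
    def _default_usual_weight(cls, data: Any) -> Any:
        if isinstance(data, dict):
            if data.get("usual_weight") in (None, ""):
                data = dict(data)
                data["usual_weight"] = data.get("current_weight")
        return data

    @field_validator("height")
    @classmethod
    def _height_in_meters(cls, v: float) -> float:
        if v > 3:
            raise ValueError(
                f"height={v} looks like centimetres; expected meters"
            )
        return v


def validate_patient(raw: Mapping[str, Any]) -> PatientInput:
    """Validate a raw field→value mapping into a :class:`PatientInput`.

    Raises :class:`PatientValidationError` naming the missing or
    out-of-range fields. Idempotent: re-validating a validated record's
    dump returns an equal record.
    """
    try:
        return PatientInput.model_validate(dict(raw))
    except pydantic.ValidationError as exc:
        fields = sorted({str(err["loc"][0]) if err["loc"] else "?" for err in exc.errors()})
        details = "; ".join(
            f"{'.'.join(str(l) for l in err['loc']) or '<record>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise PatientValidationError(
            f"invalid patient record ({details})", fields=fields
        ) from exc


class PatientClassification(BaseModel):
    """The inferred labels and derived quantities for one patient."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    phenotype: Phenotype
    copd_stage: CopdStage
    nri_value: float
    nri_class: NriClass
    sarcopenia_level: SarcopeniaLevel
    cachectic: bool
    bmi: float
    resistive_index: float
    asmm: float

    @model_validator(mode="after")
    def _cachexia_implies_sarcopenia(self) -> "PatientClassification":
        # cachexia is a particular case of sarcopenia
        if self.cachectic and self.sarcopenia_level is SarcopeniaLevel.none:
            raise ValueError("cachectic patient must be sarcopenic")
        return self


#: kcal per gram used to convert energy shares to grams.
KCAL_PER_G = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0}


class NutritionalRecommendation(BaseModel):
    """The 14-item tailored recommendation block.

    Shares are % of total daily energy; grams follow from the shares at
    4 kcal/g for protein, carbohydrate and sugar and 9 kcal/g for fat and
    saturated fat. Model validation enforces the internal consistency of
    the block: share conservation, gram conversion, and corrected energy
    at or above the basal metabolic rate.
    """

    model_config = ConfigDict(frozen=True)

    bmr_kcal: int
    energy_kcal: int
    meals_per_day: int
    energy_protein_supplement: bool
    bcaa_supplement: bool
    protein_share: float
    protein_g: float
    carb_share_min: float
    carb_share_max: float
    carb_g_min: float
    carb_g_max: float
    fat_share_min: float
    fat_share_max: float
    fat_g_min: float
    fat_g_max: float
    sugar_share_max: float
    sugar_g_max: float
    satfat_share_max: float
    satfat_g_max: float
    cholesterol_max_mg: float
    fiber_min_g: float
    fiber_max_g: float
    sodium_max_mg: float
    calcium_mg: float

    @model_validator(mode="after")
    def _consistency(self) -> "NutritionalRecommendation":
        if abs(self.protein_share + self.carb_share_max + self.fat_share_min - 100) > 0.01:
            raise ValueError("shares do not conserve: protein + carb_max + fat_min != 100")
        if abs(self.protein_share + self.carb_share_min + self.fat_share_max - 100) > 0.01:
            raise ValueError("shares do not conserve: protein + carb_min + fat_max != 100")
        e = self.energy_kcal
        conversions = [
            (self.protein_g, self.protein_share, 4.0),
            (self.carb_g_min, self.carb_share_min, 4.0),
            (self.carb_g_max, self.carb_share_max, 4.0),
            (self.fat_g_min, self.fat_share_min, 9.0),
            (self.fat_g_max, self.fat_share_max, 9.0),
            (self.sugar_g_max, self.sugar_share_max, 4.0),
            (self.satfat_g_max, self.satfat_share_max, 9.0),
        ]
        for grams, share, kcal_per_g in conversions:
            if abs(grams - share / 100.0 * e / kcal_per_g) > 0.5:
                raise ValueError("gram value inconsistent with share and energy")
        if self.sugar_share_max > 15:
            raise ValueError("sugar share cap above 15% of energy")
        if self.energy_kcal < self.bmr_kcal:
            raise ValueError("corrected energy below basal metabolic rate")
        return self


class Provenance(str, enum.Enum):
    """Whether a rule's constant comes from the published rule base or is a
    documented implementation assumption."""

    published = "published"
    assumption = "assumption"


class TraceEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    description: str
    fields: tuple[str, ...]
    provenance: Provenance = Provenance.published


class RuleTrace(BaseModel):
    """Ordered record of fired rules, the explainability contract.

    Every emitted classification/recommendation field must appear in at
    least one entry, so a report can annotate each value with the rule
    (and provenance) that produced it.
    """

    entries: tuple[TraceEntry, ...] = ()

    def add(self, rule_id: str, description: str, fields: Sequence[str],
            provenance: Provenance | str = Provenance.published) -> "RuleTrace":
        entry = TraceEntry(
            rule_id=rule_id,
            description=description,
            fields=tuple(fields),
            provenance=Provenance(provenance),
        )
        return RuleTrace(entries=self.entries + (entry,))

    def fields_covered(self) -> set[str]:
        out: set[str] = set()
        for entry in self.entries:
            out.update(entry.fields)
        return out

    def provenance_of(self, field: str) -> Provenance:
        """Provenance of the last rule that set ``field`` (assumption wins on mix)."""
        provs = [e.provenance for e in self.entries if field in e.fields]
        if not provs:
            raise KeyError(field)
        if Provenance.assumption in provs:
            return Provenance.assumption
        return Provenance.published

    def rules_for(self, field: str) -> list[str]:
        return [e.rule_id for e in self.entries if field in e.fields]
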