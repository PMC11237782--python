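"""Patient classification: BMI phenotype, COPD stage, nutritional risk
index, bioimpedance-derived muscle mass, the sarcopenia ladder and cachexia.

All cutoffs come from the rule table; interval tables are evaluated by one
generic half-open/closed interval mapper so that every band is total (no
gaps, no overlaps) over the positive reals.

Clinical background, briefly: COPD is staged I-IV on FEV1 % predicted; the
nutritional risk index ``NRI = 1.519*albumin(g/L) + 41.7*(current/usual
weight)`` screens for malnutrition; appendicular skeletal muscle mass is
estimated from the bioimpedance resistive index ``RI = height(cm)^2 /
resistance`` via the Sergi equation; sarcopenia is graded probable (low
grip strength), diagnosed (plus low muscle quantity) and severe (plus slow
gait); cachexia adds an inflammatory/biochemical triad (CRP, transferrin,
albumin) on top of sarcopenia.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from .model import (
    CopdStage,
    Gender,
    NriClass,
    PatientClassification,
    PatientInput,
    Phenotype,
    RuleTrace,
    SarcopeniaLevel,
)
from .rules import RuleBase, default_rules

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# generic interval mapping

def _in_band(x: float, band: dict) -> bool:
    if "min" in band and x < band["min"]:
        return False
    if "min_exclusive" in band and x <= band["min_exclusive"]:
        return False
    if "max" in band and x >= band["max"]:
        return False
    if "max_inclusive" in band and x > band["max_inclusive"]:
        return False
    return True


def _map_bands(x: float, bands: list[dict], label_key: str) -> str:
    hits = [b[label_key] for b in bands if _in_band(x, b)]
    if len(hits) != 1:  # totality is a structural property of the tables
        raise ClassificationError(f"value {x} matched bands {hits}")
    return hits[0]


# ---------------------------------------------------------------------------
# elementary computations

def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m². Full precision; round only for display."""
    if weight <= 0:
        raise ClassificationError("weight must be positive")
    if height <= 0:
        raise ClassificationError("height must be positive")
    return weight / height**2


def classify_phenotype(bmi: float, rules: Optional[RuleBase] = None) -> Phenotype:
    """WHO BMI band → anthropometric phenotype.

    BMI ≥ 40 classifies as obesity degree III; the recommendation rule base
    only defines five phenotype branches, so downstream it is routed to the
    obesity-II branch (a warning is logged at that point).
    """
    if bmi <= 0:
        raise ClassificationError("bmi must be positive")
    rules = rules or default_rules()
    return Phenotype(_map_bands(bmi, rules.cutoffs["bmi_phenotype"], "phenotype"))


def stage_copd(fev1_percent: float, rules: Optional[RuleBase] = None) -> CopdStage:
    """COPD stage from FEV1 % predicted: ≥80 I, [50,80) II, [30,50) III, <30 IV."""
    if fev1_percent <= 0:
        raise ClassificationError("fev1_percent must be positive")
    rules = rules or default_rules()
    return CopdStage(_map_bands(fev1_percent, rules.cutoffs["copd_stage"], "stage"))


def compute_nri(albumin: float, current_weight: float, usual_weight: float,
                rules: Optional[RuleBase] = None) -> float:
    """Nutritional risk index.

    ``albumin`` is in g/dL and converted to g/L before the 1.519
    coefficient, which is what puts the index on its ~100 scale.
    """
    if albumin <= 0 or current_weight <= 0:
        raise ClassificationError("albumin and current_weight must be positive")
    if usual_weight <= 0:
        raise ClassificationError("usual_weight must be positive")
    c = (rules or default_rules()).constants["nri"]
    return (
        c["albumin_g_per_l_coeff"] * (albumin * 10.0)
        + c["weight_ratio_coeff"] * (current_weight / usual_weight)
    )


def classify_nri(nri: float, rules: Optional[RuleBase] = None) -> NriClass:
    """Risk band: >100 absence, [97.5,100] mild, [83.5,97.5) moderate, <83.5 severe."""
    if not math.isfinite(nri):
        raise ClassificationError("nri must be finite")
    rules = rules or default_rules()
    return NriClass(_map_bands(nri, rules.cutoffs["nri_class"], "cls"))


def compute_resistive_index(height: float, resistance: float) -> float:
    """Bioimpedance resistive index, cm²/Ω: height(cm)² / resistance."""
    if resistance <= 0:
        raise ClassificationError("resistance must be positive")
    return (height * 100.0) ** 2 / resistance


def compute_asmm(ri: float, weight: float, gender: Gender, reactance: float,
                 rules: Optional[RuleBase] = None) -> float:
    """Appendicular skeletal muscle mass (kg) via the Sergi BIA equation."""
    if ri <= 0:
        raise ClassificationError("resistive index must be positive")
    c = (rules or default_rules()).constants["asmm"]
    sex = 1.0 if gender is Gender.male else 0.0
    asmm = (
        c["intercept"]
        + c["resistive_index"] * ri
        + c["weight"] * weight
        + c["male_offset"] * sex
        + c["reactance"] * reactance
    )
    if asmm <= 0:
        logger.warning("implausible non-positive ASMM %.3f kg", asmm)
    return asmm


def assess_sarcopenia(gender: Gender, hand_grip: float, asmm: float,
                      height: float, gait_speed: float,
                      rules: Optional[RuleBase] = None) -> SarcopeniaLevel:
    """Grade sarcopenia on the probable/diagnosed/severe ladder.

    Criterion 1 (low strength): grip < 27 kg (men) / 16 kg (women).
    Criterion 2 (low quantity): ASMM < 20/15 kg OR ASMM/height² < 7/5.5 kg/m².
    Criterion 3 (poor performance): gait speed ≤ 0.8 m/s.
    No criterion 1 → none; 1 alone → probable; 1+2 → diagnosed; all → severe.
    """
    cut = (rules or default_rules()).cutoffs["sarcopenia"]
    sex = gender.value
    c1 = hand_grip < cut["hand_grip_kg"][sex]
    c2 = (asmm < cut["asmm_kg"][sex]) or (asmm / height**2 < cut["asmm_over_height2"][sex])
    c3 = gait_speed <= cut["gait_speed_max"]
    if not c1:
        return SarcopeniaLevel.none
    if not c2:
        return SarcopeniaLevel.probable
    return SarcopeniaLevel.severe if c3 else SarcopeniaLevel.diagnosed


def assess_cachexia(crp: float, transferrin: float, albumin: float,
                    sarcopenia_level: SarcopeniaLevel,
                    rules: Optional[RuleBase] = None) -> bool:
    """Cachexia: sarcopenia plus CRP > 10 mg/L, transferrin < 150 mg/dL and
    albumin < 3.5 g/dL, all strict."""
    cut = (rules or default_rules()).cutoffs["cachexia"]
    return (
        sarcopenia_level is not SarcopeniaLevel.none
        and crp > cut["crp_above"]
        and transferrin < cut["transferrin_below"]
        and albumin < cut["albumin_below"]
    )


# ---------------------------------------------------------------------------
# orchestration

def classify_patient(p: PatientInput,
                     rules: Optional[RuleBase] = None
                     ) -> tuple[PatientClassification, RuleTrace]:
    """Run the full classification pipeline for one patient.

    Returns the classification together with a rule trace listing, per
    emitted field, the cutoff rule that produced it.
    """
    rules = rules or default_rules()
    trace = RuleTrace()
    try:
        bmi = compute_bmi(p.current_weight, p.height)
        phenotype = classify_phenotype(bmi, rules)
        trace = trace.add("phenotype.bmi_band",
                          f"BMI {bmi:.2f} kg/m² falls in the {phenotype.value} band",
                          ["bmi", "phenotype"])
        if phenotype is Phenotype.obesity_3:
            logger.warning(
                "patient %s: BMI %.1f ≥ 40 (obesity degree III); recommendations "
                "use the obesity-II rule branch", p.id, bmi)

        stage = stage_copd(p.fev1_percent, rules)
        trace = trace.add("stage.fev1_band",
                          f"FEV1 {p.fev1_percent:.1f}% predicted → stage {stage.value}",
                          ["copd_stage"])

        nri = compute_nri(p.albumin, p.current_weight, p.usual_weight, rules)
        nri_class = classify_nri(nri, rules)
        trace = trace.add("nri.formula",
                          "NRI = 1.519·albumin(g/L) + 41.7·(current/usual weight)",
                          ["nri_value"])
        trace = trace.add("nri.band",
                          f"NRI {nri:.2f} → {nri_class.value} risk",
                          ["nri_class"])

        ri = compute_resistive_index(p.height, p.resistance)
        asmm = compute_asmm(ri, p.current_weight, p.gender, p.reactance, rules)
        trace = trace.add("asmm.sergi",
                          "ASMM from the Sergi BIA equation on RI = height(cm)²/resistance",
                          ["resistive_index", "asmm"])

        level = assess_sarcopenia(p.gender, p.hand_grip, asmm, p.height,
                                  p.gait_speed, rules)
        trace = trace.add("sarcopenia.ladder",
                          f"grip/ASMM/gait criteria → {level.value}",
                          ["sarcopenia_level"])

        cachectic = assess_cachexia(p.crp, p.transferrin, p.albumin, level, rules)
        trace = trace.add("cachexia.triad",
                          "cachexia iff sarcopenic and CRP>10, transferrin<150, albumin<3.5",
                          ["cachectic"])
    except ClassificationError as exc:
        raise ClassificationError(f"patient {p.id}: {exc}") from exc

    classification = PatientClassification(
        patient_id=p.id,
        phenotype=phenotype,
        copd_stage=stage,
        nri_value=nri,
        nri_class=nri_class,
        sarcopenia_level=level,
        cachectic=cachectic,
        bmi=bmi,
        resistive_index=ri,
        asmm=asmm,
    )
    return classification, trace
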