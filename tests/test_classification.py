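"""Unit and property tests for the classification computations.

The brute-force nested-conditional oracles here re-state each published
cutoff table independently of the interval-map implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nutricopd as nc
from nutricopd.classify import ClassificationError

from conftest import patient

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")


# --------------------------------------------------------------------------
# independent oracles (plain nested conditionals)

def oracle_phenotype(bmi):
    if bmi < 18.5:
        return "underweight"
    elif bmi <= 24.9 or bmi < 25.0:
        return "normal_weight"
    elif bmi < 30.0:
        return "overweight"
    elif bmi < 35.0:
        return "obesity_1"
    elif bmi < 40.0:
        return "obesity_2"
    else:
        return "obesity_3"


def oracle_stage(fev1):
    if fev1 >= 80:
        return "I"
    elif fev1 >= 50:
        return "II"
    elif fev1 >= 30:
        return "III"
    else:
        return "IV"


def oracle_nri_class(nri):
    if nri > 100:
        return "absence"
    elif nri >= 97.5:
        return "mild"
    elif nri >= 83.5:
        return "moderate"
    else:
        return "severe"


def oracle_sarcopenia(gender, grip, asmm, height, gait):
    grip_cut = 27 if gender == "male" else 16
    asmm_cut = 20 if gender == "male" else 15
    ratio_cut = 7.0 if gender == "male" else 5.5
    c1 = grip < grip_cut
    c2 = asmm < asmm_cut or asmm / height**2 < ratio_cut
    c3 = gait <= 0.8
    if not c1:
        return "none"
    if not c2:
        return "probable"
    return "severe" if c3 else "diagnosed"


# --------------------------------------------------------------------------
# worked values

@pytest.mark.parametrize("weight,height,expected", [
    (70, 1.75, 22.86), (25, 1.0, 25.0),
])
def test_bmi_examples(weight, height, expected):
    assert round(nc.compute_bmi(weight, height), 2) == expected


def test_bmi_preconditions():
    with pytest.raises(ClassificationError):
        nc.compute_bmi(0, 1.7)
    with pytest.raises(ClassificationError):
        nc.compute_bmi(70, 0)


@pytest.mark.parametrize("bmi,expected", [
    (18.4, "underweight"), (18.5, "normal_weight"), (24.95, "normal_weight"),
    (25.0, "overweight"), (30.0, "obesity_1"), (35.0, "obesity_2"),
    (40.0, "obesity_3"), (42.0, "obesity_3"),
])
def test_phenotype_bands(bmi, expected):
    assert nc.classify_phenotype(bmi).value == expected


@pytest.mark.parametrize("fev1,expected", [
    (80, "I"), (79.9, "II"), (50, "II"), (49.9, "III"),
    (30, "III"), (29.9, "IV"),
])
def test_copd_stage_bands(fev1, expected):
    assert nc.stage_copd(fev1).value == expected


@pytest.mark.parametrize("albumin,cw,uw,expected", [
    (4.0, 60, 60, 102.46), (3.0, 54, 60, 83.10),
])
def test_nri_worked_values(albumin, cw, uw, expected):
    assert round(nc.compute_nri(albumin, cw, uw), 2) == expected


def test_nri_albumin_limit_leaves_weight_term():
    # as albumin -> 0 the index tends to 41.7 x weight ratio
    assert nc.compute_nri(1e-9, 54, 60) == pytest.approx(41.7 * 0.9, abs=1e-6)


@pytest.mark.parametrize("nri,expected", [
    (100.1, "absence"), (100.0, "mild"), (97.5, "mild"),
    (97.49, "moderate"), (83.5, "moderate"), (83.49, "severe"),
])
def test_nri_bands(nri, expected):
    assert nc.classify_nri(nri).value == expected


def test_resistive_index_worked_values():
    assert nc.compute_resistive_index(1.75, 500) == pytest.approx(61.25)
    assert nc.compute_resistive_index(1.0, 100) == pytest.approx(100.0)
    with pytest.raises(ClassificationError):
        nc.compute_resistive_index(1.6, 0)


@pytest.mark.parametrize("gender,expected", [
    (nc.Gender.male, 21.17), (nc.Gender.female, 19.79),
])
def test_asmm_worked_values(gender, expected):
    assert round(nc.compute_asmm(61.25, 70, gender, 50), 2) == expected


@pytest.mark.parametrize("gender,grip,asmm,height,gait,expected", [
    ("male", 27, 25, 1.75, 1.2, "none"),       # at the cutoff is not below it
    ("female", 15, 14, 1.6, 0.9, "diagnosed"),
    ("male", 20, 21, 1.75, 0.8, "severe"),     # 21/1.75^2 < 7 triggers the OR
    ("male", 20, 22, 1.75, 0.9, "probable"),
])
def test_sarcopenia_ladder_cases(gender, grip, asmm, height, gait, expected):
    level = nc.assess_sarcopenia(nc.Gender(gender), grip, asmm, height, gait)
    assert level.value == expected


@pytest.mark.parametrize("crp,tf,alb,level,expected", [
    (11, 140, 3.4, "diagnosed", True),
    (11, 140, 3.4, "none", False),
    (10, 140, 3.4, "severe", False),  # 10 is not > 10
    (11, 150, 3.4, "severe", False),
    (11, 140, 3.5, "severe", False),
])
def test_cachexia_criteria(crp, tf, alb, level, expected):
    got = nc.assess_cachexia(crp, tf, alb, nc.SarcopeniaLevel(level))
    assert got is expected


# --------------------------------------------------------------------------
# properties

@given(st.floats(min_value=10, max_value=60))
def test_phenotype_matches_oracle(bmi):
    assert nc.classify_phenotype(bmi).value == oracle_phenotype(bmi)


@given(st.floats(min_value=1, max_value=150))
def test_stage_matches_oracle(fev1):
    assert nc.stage_copd(fev1).value == oracle_stage(fev1)


@given(st.floats(min_value=30, max_value=130))
def test_nri_class_matches_oracle(nri):
    assert nc.classify_nri(nri).value == oracle_nri_class(nri)


@given(st.sampled_from(["male", "female"]),
       st.floats(min_value=0, max_value=60),
       st.floats(min_value=1, max_value=40),
       st.floats(min_value=1.4, max_value=2.0),
       st.floats(min_value=0, max_value=2))
def test_sarcopenia_matches_oracle(gender, grip, asmm, height, gait):
    got = nc.assess_sarcopenia(nc.Gender(gender), grip, asmm, height, gait)
    assert got.value == oracle_sarcopenia(gender, grip, asmm, height, gait)


@given(st.floats(min_value=2, max_value=5), st.floats(min_value=0.1, max_value=5),
       st.floats(min_value=40, max_value=120), st.floats(min_value=40, max_value=120))
def test_nri_strictly_increasing_in_albumin_and_ratio(alb, dalb, cw, uw):
    base = nc.compute_nri(alb, cw, uw)
    assert nc.compute_nri(alb + dalb, cw, uw) > base
    assert nc.compute_nri(alb, cw * 1.05, uw) > base


@given(st.floats(min_value=20, max_value=120), st.floats(min_value=40, max_value=150),
       st.floats(min_value=0, max_value=100))
def test_asmm_strictly_increasing_in_ri_weight_reactance(ri, weight, xc):
    base = nc.compute_asmm(ri, weight, nc.Gender.female, xc)
    assert nc.compute_asmm(ri + 1, weight, nc.Gender.female, xc) > base
    assert nc.compute_asmm(ri, weight + 1, nc.Gender.female, xc) > base
    assert nc.compute_asmm(ri, weight, nc.Gender.female, xc + 1) > base
    assert nc.compute_asmm(ri, weight, nc.Gender.male, xc) > base


@given(st.sampled_from(["male", "female"]),
       st.floats(min_value=0, max_value=60),
       st.floats(min_value=1, max_value=40),
       st.floats(min_value=1.4, max_value=2.0),
       st.floats(min_value=0, max_value=2))
def test_ladder_is_nested(gender, grip, asmm, height, gait):
    """severe satisfies the diagnosed criteria, diagnosed the probable ones."""
    g = nc.Gender(gender)
    level = nc.assess_sarcopenia(g, grip, asmm, height, gait)
    if level in (nc.SarcopeniaLevel.diagnosed, nc.SarcopeniaLevel.severe):
        # dropping criterion 3 (fast gait) never drops below diagnosed
        assert nc.assess_sarcopenia(g, grip, asmm, height, 1.5) in (
            nc.SarcopeniaLevel.diagnosed, nc.SarcopeniaLevel.severe)
    if level is not nc.SarcopeniaLevel.none:
        # criterion 1 held: forcing criteria 2+3 yields severe
        assert nc.assess_sarcopenia(g, grip, 1.0, height, 0.5) is \
            nc.SarcopeniaLevel.severe


def test_classification_is_total_on_random_grid(rules):
    rng = np.random.default_rng(7)
    for bmi in rng.uniform(10, 60, 500):
        nc.classify_phenotype(float(bmi), rules)
    for fev1 in np.append(rng.uniform(1, 130, 500), [30.0, 50.0, 80.0]):
        nc.stage_copd(float(fev1), rules)
    for nri in np.append(rng.uniform(40, 130, 500), [83.5, 97.5, 100.0]):
        nc.classify_nri(float(nri), rules)


def test_classify_patient_all_negative_case():
    p = patient(fev1_percent=85)
    cls, trace = nc.classify_patient(p)
    assert (cls.phenotype, cls.copd_stage, cls.nri_class,
            cls.sarcopenia_level, cls.cachectic) == (
        nc.Phenotype.normal_weight, nc.CopdStage.I, nc.NriClass.absence,
        nc.SarcopeniaLevel.none, False)
    emitted = {"bmi", "phenotype", "copd_stage", "nri_value", "nri_class",
               "resistive_index", "asmm", "sarcopenia_level", "cachectic"}
    assert emitted <= trace.fields_covered()


def test_classify_patient_attaches_patient_id_to_errors():
    bad = nc.PatientInput.model_construct(
        id="broken", gender=nc.Gender.male, age=64, current_weight=70.0,
        usual_weight=70.0, height=-1.0, fev1_percent=65.0, hand_grip=40.0,
        gait_speed=1.2, resistance=500.0, reactance=50.0, albumin=4.0,
        crp=2.0, transferrin=250.0, pco2=None, has_t2dm=False,
        has_hypercholesterolemia=False)
    with pytest.raises(ClassificationError, match="broken"):
        nc.classify_patient(bad)
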