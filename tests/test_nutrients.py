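"""Nutrient rule-base tests, including the independent flat decision-table
oracle swept over the full classification lattice."""

import pytest

import nutricopd as nc
from nutricopd.nutrients import InfeasibleShareError

from conftest import patient


def classification(phenotype="normal_weight", stage="II", level="none",
                   cachectic=False, **kw):
    return nc.PatientClassification(
        patient_id="t", phenotype=nc.Phenotype(phenotype),
        copd_stage=nc.CopdStage(stage), nri_value=kw.get("nri", 102.0),
        nri_class=nc.NriClass(kw.get("nri_class", "absence")),
        sarcopenia_level=nc.SarcopeniaLevel(level), cachectic=cachectic,
        bmi=kw.get("bmi", 22.0), resistive_index=60.0, asmm=kw.get("asmm", 22.0))


# --------------------------------------------------------------------------
# independent oracle: the decision tables as flat conditionals

def oracle_protein_g(phenotype, level, cachectic, energy, weight, height):
    if cachectic:
        return 0.25 * energy / 4.0
    mult = 1.5 if level != "none" else 1.2
    if phenotype == "underweight":
        basis = 22.5 * height**2
    elif phenotype in ("normal_weight", "overweight"):
        basis = weight
    else:  # any obesity class
        basis = 25.0 * height**2
    return mult * basis


def oracle_supplements(phenotype, level, cachectic):
    if cachectic:
        return True, True
    if level != "none":
        if phenotype in ("underweight", "normal_weight"):
            return True, True
        return True, False
    return False, False


def oracle_factor(stage, cachectic):
    return 1.8 if (cachectic or stage in ("III", "IV")) else 1.5


# --------------------------------------------------------------------------
# worked values

def test_protein_normal_weight_non_sarcopenic():
    grams, share, row = nc.protein_targets(classification(), 2205, 70, 1.75)
    assert grams == pytest.approx(84.0)
    assert share == pytest.approx(15.24, abs=0.01)
    assert row["id"] == "protein.normal_overweight"


def test_protein_cachectic_fixed_share():
    cls = classification(level="diagnosed", cachectic=True)
    grams, share, _ = nc.protein_targets(cls, 2000, 70, 1.75)
    assert share == 25.0
    assert grams == pytest.approx(125.0)


def test_protein_underweight_uses_reference_bmi():
    cls = classification(phenotype="underweight", bmi=17.0)
    grams, _, row = nc.protein_targets(cls, 2205, 52.0, 1.75)
    assert grams == pytest.approx(1.2 * 22.5 * 1.75**2)  # 82.7 g
    assert round(grams, 1) == 82.7
    assert row["basis"] == "reference_bmi"


def test_protein_requires_positive_energy():
    with pytest.raises(InfeasibleShareError):
        nc.protein_targets(classification(), 0, 70, 1.75)


def test_shares_conserve_without_lipid_boost():
    s = nc.energy_shares(15.2, pco2=None, has_t2dm=False)
    assert (s["carb_share_min"], s["carb_share_max"]) == (45, 50)
    assert s["fat_share_min"] == pytest.approx(34.8)
    assert s["fat_share_max"] == pytest.approx(39.8)
    assert s["sugar_share_max"] == 15 and s["satfat_share_max"] == 10


def test_lipid_boost_shifts_carbohydrate_band():
    s = nc.energy_shares(25.0, pco2=55, has_t2dm=False)
    assert (s["carb_share_min"], s["carb_share_max"]) == (40, 45)
    assert s["fat_share_min"] == pytest.approx(30.0)
    assert s["fat_share_max"] == pytest.approx(35.0)
    # pCO2 at the threshold does not trigger the boost
    assert nc.energy_shares(25.0, pco2=50, has_t2dm=False)["carb_share_max"] == 50


def test_t2dm_halves_sugar_cap():
    assert nc.energy_shares(15.0, None, has_t2dm=True)["sugar_share_max"] == 10


def test_infeasible_protein_share_raises():
    with pytest.raises(InfeasibleShareError):
        nc.energy_shares(56.0, pco2=None, has_t2dm=False)


def test_micronutrient_caps():
    caps = nc.micronutrient_caps(False)
    assert caps == {"cholesterol_max_mg": 300, "sodium_max_mg": 2000,
                    "calcium_mg": 1200, "fiber_min_g": 15, "fiber_max_g": 25}
    assert nc.micronutrient_caps(True)["cholesterol_max_mg"] == 200
    assert nc.micronutrient_caps(True)["sodium_max_mg"] == 2000


@pytest.mark.parametrize("phenotype,level,cachectic,expected", [
    ("obesity_1", "diagnosed", True, (True, True)),
    ("overweight", "probable", False, (True, False)),
    ("underweight", "severe", False, (True, True)),
    ("normal_weight", "none", False, (False, False)),
])
def test_supplementation_flags(phenotype, level, cachectic, expected):
    cls = classification(phenotype=phenotype, level=level, cachectic=cachectic)
    bcaa, ep, _ = nc.supplementation_flags(cls)
    assert (bcaa, ep) == expected


def test_assembled_recommendation_worked_example(demo_patient):
    cls, rec, trace = nc.recommend(demo_patient)
    assert rec.bmr_kcal == 1470 and rec.energy_kcal == 2205
    assert rec.protein_g == pytest.approx(84.0)
    assert rec.carb_g_min == pytest.approx(248.1, abs=0.1)
    assert rec.carb_g_max == pytest.approx(275.6, abs=0.1)
    assert rec.sodium_max_mg == 2000 and rec.meals_per_day == 5
    # determinism: identical input → identical serialized output
    cls2, rec2, trace2 = nc.recommend(demo_patient)
    assert rec2 == rec and cls2 == cls and trace2 == trace


def test_cachexia_rules_co_fire():
    p = patient(albumin=3.2, crp=20, transferrin=100, hand_grip=20,
                gait_speed=0.5, resistance=900)
    cls, rec, _ = nc.recommend(p)
    assert cls.cachectic
    assert rec.energy_kcal == nc.corrected_energy(rec.bmr_kcal, 1.8)
    assert rec.protein_share == 25.0
    assert rec.bcaa_supplement and rec.energy_protein_supplement


# --------------------------------------------------------------------------
# lattice sweep against the flat oracle

def test_lattice_complete_and_matches_decision_table_oracle(classified_lattice):
    for p, cls, rec, trace in classified_lattice:
        phen = ("obesity_2" if cls.phenotype is nc.Phenotype.obesity_3
                else cls.phenotype.value)
        level, cach = cls.sarcopenia_level.value, cls.cachectic
        # every recommendation field is assigned and traced exactly once
        covered = trace.fields_covered()
        for field in nc.NutritionalRecommendation.model_fields:
            assert field in covered, f"{p.id}: untraced field {field}"
            assert len(trace.rules_for(field)) >= 1
        # energy factor
        want_factor = oracle_factor(cls.copd_stage.value, cach)
        assert rec.energy_kcal == nc.corrected_energy(rec.bmr_kcal, want_factor), p.id
        # protein
        want_g = oracle_protein_g(phen, level, cach, rec.energy_kcal,
                                  p.current_weight, p.height)
        assert rec.protein_g == pytest.approx(want_g), p.id
        # supplements
        assert (rec.bcaa_supplement, rec.energy_protein_supplement) == \
            oracle_supplements(phen, level, cach), p.id
        # cachexia dominance
        if cach:
            assert rec.protein_share == 25.0 and rec.bcaa_supplement \
                and rec.energy_protein_supplement


def test_share_and_gram_identities_on_lattice(classified_lattice):
    for p, cls, rec, _ in classified_lattice:
        assert rec.protein_share + rec.carb_share_max + rec.fat_share_min == \
            pytest.approx(100, abs=0.01), p.id
        assert rec.protein_share + rec.carb_share_min + rec.fat_share_max == \
            pytest.approx(100, abs=0.01), p.id
        e = rec.energy_kcal
        assert rec.carb_g_max == pytest.approx(rec.carb_share_max / 100 * e / 4)
        assert rec.fat_g_min == pytest.approx(rec.fat_share_min / 100 * e / 9)
        assert rec.sugar_g_max == pytest.approx(rec.sugar_share_max / 100 * e / 4)
        assert e >= rec.bmr_kcal


def test_rule_table_completeness_validation(rules):
    rules.validate_completeness()  # packaged table covers the lattice
    import copy
    broken = copy.deepcopy(dict(rules.raw))
    broken["protein"]["rules"] = [r for r in broken["protein"]["rules"]
                                  if r["id"] != "protein.obese"]
    from nutricopd.rules import RuleBase, RuleTableError
    with pytest.raises(RuleTableError):
        RuleBase(raw=broken).validate_completeness()
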