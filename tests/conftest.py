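import logging

import pytest

import nutricopd as nc


@pytest.fixture(autouse=True)
def _quiet_obesity3_warnings(caplog):
    # obesity-III routing warnings are expected in lattice sweeps
    logging.getLogger("nutricopd").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def rules():
    return nc.default_rules()


def patient(**overrides) -> nc.PatientInput:
    """A healthy normal-weight stage-II male; override fields per test."""
    base = dict(
        id="t", gender="male", age=64, current_weight=70, usual_weight=70,
        height=1.75, fev1_percent=65, hand_grip=40, gait_speed=1.2,
        resistance=500, reactance=50, albumin=4.0, crp=2.0, transferrin=250.0,
    )
    base.update(overrides)
    return nc.validate_patient(base)


@pytest.fixture()
def demo_patient():
    return patient()


@pytest.fixture(scope="session")
def archetypes(rules):
    return nc.generate_archetypes(rules)


@pytest.fixture(scope="session")
def classified_lattice(archetypes, rules):
    """Every archetype with its classification, recommendation and trace."""
    out = []
    for p in archetypes:
        cls, rec, trace = nc.recommend(p, rules)
        out.append((p, cls, rec, trace))
    return out
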