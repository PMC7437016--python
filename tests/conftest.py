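import pytest

from petriage import PatientRecord


def make_record(**overrides) -> PatientRecord:
    """A valid baseline patient with every clinical item off."""
    base = dict(
        patient_id="p1", age=60, heart_rate=80.0, sao2=96.0, d_dimer=300.0,
        dvt_signs=False, pe_most_likely=False, hemoptysis=False,
        recent_immobilization=False, recent_surgery=False, recent_trauma=False,
        history_vte=False, active_cancer=False, oral_hormone_use=False,
        unilateral_leg_swelling=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
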