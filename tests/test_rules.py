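"""Rule engines: boundary cases, an exhaustive truth-table oracle, and
set-nesting / monotonicity properties."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from petriage import (ALGORITHMS, CohortTable, TriageConfig, Verdict,
                      age_adjusted_algorithm, compute_wells_score,
                      peged_algorithm, perc_algorithm, run_all,
                      standard_algorithm, years_algorithm)
from petriage.wells import classify_three_level

from conftest import make_record

CFG = TriageConfig()


def cptp(rec):
    return classify_three_level(compute_wells_score(rec, CFG.wells), CFG.scheme).value


# --- independent clause re-statements (the oracle) -----------------------

def oracle_standard(rec):
    return cptp(rec) == "low" and rec.d_dimer < 500


def oracle_age_adjusted(rec):
    cutoff = rec.age * 10 if rec.age > 50 else 500
    return cptp(rec) in ("low", "moderate") and rec.d_dimer < cutoff


def oracle_years(rec):
    items = rec.dvt_signs + rec.hemoptysis + rec.pe_most_likely
    return rec.d_dimer < (1000 if items == 0 else 500)


def oracle_perc(rec):
    return (rec.age < 50 and rec.sao2 > 94 and rec.heart_rate < 100
            and not rec.hemoptysis and not (rec.recent_trauma or rec.recent_surgery)
            and not rec.history_vte and not rec.unilateral_leg_swelling
            and not rec.oral_hormone_use)


def oracle_peged(rec):
    c = cptp(rec)
    return (c == "low" and rec.d_dimer < 1000) or (c == "moderate" and rec.d_dimer < 500)


ORACLES = {
    "standard": oracle_standard, "age_adjusted": oracle_age_adjusted,
    "years": oracle_years, "perc": oracle_perc, "peged": oracle_peged,
}

GRID_FLAGS = ["dvt_signs", "pe_most_likely", "hemoptysis", "recent_surgery",
              "history_vte", "oral_hormone_use", "unilateral_leg_swelling"]


def grid_records():
    """>= 2^7 x 5 x 8 x 3 x 3 boundary-straddling inputs."""
    i = 0
    for bits in itertools.product([False, True], repeat=len(GRID_FLAGS)):
        flags = dict(zip(GRID_FLAGS, bits))
        for age in (30, 49, 50, 51, 80):
            for dd in (0, 499, 500, 799, 800, 999, 1000, 1500):
                for hr in (80, 100, 120):
                    for sao2 in (90, 94, 95):
                        i += 1
                        yield make_record(patient_id=f"g{i}", age=age,
                                          d_dimer=float(dd), heart_rate=float(hr),
                                          sao2=float(sao2), **flags)


def test_all_engines_agree_with_truth_table_oracle():
    n = 0
    for rec in grid_records():
        for name, engine in ALGORITHMS.items():
            decision = engine(rec, CFG)
            assert decision.ruled_out == ORACLES[name](rec), (name, rec)
        n += 1
    assert n == 2**7 * 5 * 8 * 3 * 3


def test_remaining_booleans_covered_by_oracle():
    # immobilization / trauma / cancer vary on a focused sub-grid
    for immob, trauma, cancer in itertools.product([False, True], repeat=3):
        for dd in (499.0, 500.0, 999.0, 1000.0):
            rec = make_record(recent_immobilization=immob, recent_trauma=trauma,
                              active_cancer=cancer, age=45, d_dimer=dd)
            for name, engine in ALGORITHMS.items():
                assert engine(rec, CFG).ruled_out == ORACLES[name](rec)


# --- spec'd boundary examples --------------------------------------------

@pytest.mark.parametrize("engine, kwargs, ruled_out", [
    (standard_algorithm, dict(d_dimer=499.0), True),
    (standard_algorithm, dict(d_dimer=500.0), False),            # tie goes to imaging
    (standard_algorithm, dict(d_dimer=100.0, dvt_signs=True, pe_most_likely=True,
                              history_vte=True), False),         # high C-PTP
    (age_adjusted_algorithm, dict(age=80, d_dimer=750.0, dvt_signs=True,
                                  recent_surgery=True), True),   # cutoff 800, moderate
    (age_adjusted_algorithm, dict(age=80, d_dimer=800.0, dvt_signs=True,
                                  recent_surgery=True), False),
    (age_adjusted_algorithm, dict(age=45, d_dimer=600.0), False),  # <=50 keeps 500
    (age_adjusted_algorithm, dict(age=50, d_dimer=600.0), False),  # 50 is "younger"
    (age_adjusted_algorithm, dict(age=51, d_dimer=509.0), True),   # 51 -> 510
    (years_algorithm, dict(d_dimer=999.0), True),
    (years_algorithm, dict(d_dimer=1000.0), False),
    (years_algorithm, dict(d_dimer=600.0, hemoptysis=True), False),
    (years_algorithm, dict(d_dimer=499.0, hemoptysis=True), True),
    (perc_algorithm, dict(age=45), True),
    (perc_algorithm, dict(age=67), False),
    (perc_algorithm, dict(age=49, sao2=94.0), False),            # SaO2 must exceed 94
    (perc_algorithm, dict(age=49, heart_rate=100.0), False),     # pulse strictly < 100
    (peged_algorithm, dict(d_dimer=999.0), True),                # low & <1000
    (peged_algorithm, dict(d_dimer=499.0, dvt_signs=True, recent_surgery=True), True),
    (peged_algorithm, dict(d_dimer=200.0, dvt_signs=True, pe_most_likely=True,
                           history_vte=True), False),            # high C-PTP
])
def test_boundary_examples(engine, kwargs, ruled_out):
    rec = make_record(age=kwargs.pop("age", 60), **kwargs)
    decision = engine(rec, CFG)
    assert decision.ruled_out is ruled_out, decision.fired_clause


def test_perc_lists_every_failed_criterion():
    rec = make_record(age=67, sao2=90.0, heart_rate=110.0, hemoptysis=True)
    clause = perc_algorithm(rec, CFG).fired_clause
    for fragment in ("age", "SaO2", "pulse", "hemoptysis"):
        assert fragment in clause


def test_over50_cptp_clause_is_configurable(record_factory):
    rec = record_factory(age=80, d_dimer=700.0, dvt_signs=True, pe_most_likely=True,
                         history_vte=True)  # high C-PTP, cutoff 800
    assert not age_adjusted_algorithm(rec, CFG).ruled_out
    relaxed = TriageConfig(age_adjusted_requires_cptp_over_50=False)
    assert age_adjusted_algorithm(rec, relaxed).ruled_out


def test_perc_leg_swelling_can_derive_from_dvt_signs(record_factory):
    rec = record_factory(age=40, dvt_signs=True)
    assert perc_algorithm(rec, CFG).ruled_out            # distinct fields by default
    derived = TriageConfig(perc_leg_swelling_from_dvt_signs=True)
    assert not perc_algorithm(rec, derived).ruled_out


# --- properties -----------------------------------------------------------

record_strategy = st.builds(
    make_record,
    patient_id=st.just("h"),
    age=st.integers(18, 100),
    heart_rate=st.floats(40, 180),
    sao2=st.floats(50, 100),
    d_dimer=st.floats(0, 5000),
    **{f: st.booleans() for f in GRID_FLAGS + ["recent_immobilization",
                                               "recent_trauma", "active_cancer"]},
)


@settings(max_examples=300, derandomize=True)
@given(record_strategy)
def test_rule_out_set_nesting(rec):
    """Anyone the standard strategy clears is also cleared by the graduated
    and age-adjusted strategies (their imaging sets nest inside standard's)."""
    if standard_algorithm(rec, CFG).ruled_out:
        assert peged_algorithm(rec, CFG).ruled_out
        assert age_adjusted_algorithm(rec, CFG).ruled_out


@settings(max_examples=100, derandomize=True)
@given(record_strategy)
def test_d_dimer_monotonicity(rec):
    """Raising D-dimer never converts imaging into rule-out."""
    ladder = sorted((0.0, 499.0, 500.0, rec.age * 10.0, 999.0, 1000.0, 4000.0))
    for engine in ALGORITHMS.values():
        verdicts = [engine(rec.model_copy(update={"d_dimer": dd}), CFG).ruled_out
                    for dd in ladder]
        assert verdicts == sorted(verdicts, reverse=True)  # no rule-out after imaging


def test_run_all_cardinality_and_errors(record_factory):
    cohort = CohortTable([record_factory(patient_id="a"), record_factory(patient_id="b")])
    table = run_all(cohort, CFG)
    assert sum(len(v) for v in table.values()) == 2 * 5
    assert run_all(cohort, CFG, []) == {}
    with pytest.raises(ValueError, match="geneva"):
        run_all(cohort, CFG, ["geneva"])


def test_determinism(record_factory):
    rec = record_factory(d_dimer=640.0, dvt_signs=True)
    for engine in ALGORITHMS.values():
        assert engine(rec, CFG) == engine(rec, CFG)
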