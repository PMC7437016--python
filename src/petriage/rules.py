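"""The five PE-likelihood triage algorithms as pure decision functions.

Each engine maps one :class:`~petriage.records.PatientRecord` (plus a
:class:`TriageConfig`) to a binary verdict — ``rule_out`` (PE excluded, no
imaging) or ``imaging_required`` (PE not excluded; CTPA and/or V/Q scan
warranted).  All D-dimer comparisons are strict ("less than"); ties at a
cutoff go to imaging.  No engine consults the ``confirmed_pe`` reference
standard.

Engines
-------
standard
    Rule out iff low C-PTP and D-dimer < 500 ng/ml.
age_adjusted
    Cutoff 500 ng/ml up to age 50, else age x 10 ng/ml; rule out iff
    C-PTP is low or moderate and D-dimer is under the effective cutoff.
years
    Three items (DVT signs, hemoptysis, PE most likely): none firing ->
    cutoff 1000 ng/ml, one or more -> 500 ng/ml.
perc
    Rule out iff all eight hold: age < 50, SaO2 > 94%, pulse < 100, no
    hemoptysis, no recent trauma or surgery, no VTE history, no unilateral
    leg swelling, no oral hormone use.
peged
    Graduated D-dimer: low C-PTP & < 1000 ng/ml, or moderate C-PTP &
    < 500 ng/ml; high C-PTP always goes to imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Dict, Iterable, Optional, Sequence

import pandas as pd

from .records import CohortTable, PatientRecord
from .wells import Cptp, CptpScheme, WellsWeights, classify_three_level, compute_wells_score

__all__ = [
    "Verdict",
    "TriageConfig",
    "AlgorithmDecision",
    "standard_algorithm",
    "age_adjusted_algorithm",
    "years_algorithm",
    "perc_algorithm",
    "peged_algorithm",
    "ALGORITHMS",
    "run_all",
    "decisions_to_frame",
]


class Verdict(str, Enum):
    RULE_OUT = "rule_out"
    IMAGING_REQUIRED = "imaging_required"


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds and cut-points shared by all engines.

    D-dimer cutoffs in ng/ml; PERC limits are exclusive bounds
    (age < 50, pulse < 100, SaO2 > 94).
    """

    d_dimer_standard_cutoff: float = 500.0
    d_dimer_high_cutoff: float = 1000.0
    age_adjust_factor: float = 10.0     # ng/ml per year, applied strictly above min age
    age_adjust_min_age: int = 50
    perc_age_max: float = 50.0
    perc_pulse_max: float = 100.0
    perc_sao2_min: float = 94.0
    age_adjusted_requires_cptp_over_50: bool = True
    perc_leg_swelling_from_dvt_signs: bool = False
    wells: WellsWeights = field(default_factory=WellsWeights)
    scheme: CptpScheme = field(default_factory=CptpScheme)

    def __post_init__(self):
        if not (0 < self.d_dimer_standard_cutoff <= self.d_dimer_high_cutoff):
            raise ValueError("require 0 < d_dimer_standard_cutoff <= d_dimer_high_cutoff")
        if min(self.age_adjust_factor, self.perc_age_max,
               self.perc_pulse_max, self.perc_sao2_min) <= 0:
            raise ValueError("all triage limits must be positive")


@dataclass(frozen=True)
class AlgorithmDecision:
    """Per-patient verdict of one algorithm, with the clause that fired."""

    patient_id: str
    algorithm: str
    verdict: Verdict
    fired_clause: str
    cptp_category: Optional[str] = None
    d_dimer: Optional[float] = None
    threshold_applied: Optional[float] = None

    @property
    def ruled_out(self) -> bool:
        return self.verdict is Verdict.RULE_OUT


def _cptp(record: PatientRecord, config: TriageConfig) -> Cptp:
    score = compute_wells_score(record, config.wells)
    return classify_three_level(score, config.scheme)


def standard_algorithm(record: PatientRecord, config: TriageConfig = TriageConfig()) -> AlgorithmDecision:
    """Rule out iff low C-PTP and D-dimer < the standard cutoff (500 ng/ml)."""
    cat = _cptp(record, config)
    cutoff = config.d_dimer_standard_cutoff
    if cat is Cptp.LOW and record.d_dimer < cutoff:
        clause = f"low C-PTP and D-dimer {record.d_dimer:g} < {cutoff:g} ng/ml"
        verdict = Verdict.RULE_OUT
    elif cat is not Cptp.LOW:
        clause = f"C-PTP is {cat.value}, not low"
        verdict = Verdict.IMAGING_REQUIRED
    else:
        clause = f"D-dimer {record.d_dimer:g} >= {cutoff:g} ng/ml"
        verdict = Verdict.IMAGING_REQUIRED
    return AlgorithmDecision(record.patient_id, "standard", verdict, clause,
                             cat.value, record.d_dimer, cutoff)


def age_adjusted_algorithm(record: PatientRecord, config: TriageConfig = TriageConfig()) -> AlgorithmDecision:
    """Age-adjusted D-dimer cutoff: 500 ng/ml at age <= 50, else age x 10."""
    cat = _cptp(record, config)
    if record.age > config.age_adjust_min_age:
        cutoff = record.age * config.age_adjust_factor
        cptp_required = config.age_adjusted_requires_cptp_over_50
    else:
        cutoff = config.d_dimer_standard_cutoff
        cptp_required = True
    cptp_ok = (cat in (Cptp.LOW, Cptp.MODERATE)) or not cptp_required
    if cptp_ok and record.d_dimer < cutoff:
        clause = (f"C-PTP {cat.value} and D-dimer {record.d_dimer:g} < "
                  f"age-adjusted cutoff {cutoff:g} ng/ml")
        verdict = Verdict.RULE_OUT
    elif not cptp_ok:
        clause = f"C-PTP is {cat.value}, not low/moderate"
        verdict = Verdict.IMAGING_REQUIRED
    else:
        clause = f"D-dimer {record.d_dimer:g} >= cutoff {cutoff:g} ng/ml"
        verdict = Verdict.IMAGING_REQUIRED
    return AlgorithmDecision(record.patient_id, "age_adjusted", verdict, clause,
                             cat.value, record.d_dimer, cutoff)


def years_algorithm(record: PatientRecord, config: TriageConfig = TriageConfig()) -> AlgorithmDecision:
    """Item-count-graduated cutoff: 0 items -> 1000 ng/ml, >= 1 -> 500 ng/ml."""
    items = sum((record.dvt_signs, record.hemoptysis, record.pe_most_likely))
    cutoff = config.d_dimer_high_cutoff if items == 0 else config.d_dimer_standard_cutoff
    if record.d_dimer < cutoff:
        clause = f"{items} item(s) and D-dimer {record.d_dimer:g} < {cutoff:g} ng/ml"
        verdict = Verdict.RULE_OUT
    else:
        clause = f"{items} item(s) and D-dimer {record.d_dimer:g} >= {cutoff:g} ng/ml"
        verdict = Verdict.IMAGING_REQUIRED
    return AlgorithmDecision(record.patient_id, "years", verdict, clause,
                             str(items), record.d_dimer, cutoff)


def perc_algorithm(record: PatientRecord, config: TriageConfig = TriageConfig()) -> AlgorithmDecision:
    """Rule out only when all eight PERC criteria are met (no D-dimer)."""
    leg_swelling = record.unilateral_leg_swelling
    if config.perc_leg_swelling_from_dvt_signs:
        leg_swelling = leg_swelling or record.dvt_signs
    failed = []
    if not record.age < config.perc_age_max:
        failed.append(f"age {record.age} >= {config.perc_age_max:g}")
    if not record.sao2 > config.perc_sao2_min:
        failed.append(f"SaO2 {record.sao2:g} <= {config.perc_sao2_min:g}%")
    if not record.heart_rate < config.perc_pulse_max:
        failed.append(f"pulse {record.heart_rate:g} >= {config.perc_pulse_max:g}")
    if record.hemoptysis:
        failed.append("hemoptysis")
    if record.recent_trauma or record.recent_surgery:
        failed.append("recent trauma or surgery")
    if record.history_vte:
        failed.append("history of VTE")
    if leg_swelling:
        failed.append("unilateral leg swelling")
    if record.oral_hormone_use:
        failed.append("oral hormone use")
    if failed:
        verdict = Verdict.IMAGING_REQUIRED
        clause = "failed: " + "; ".join(failed)
    else:
        verdict = Verdict.RULE_OUT
        clause = "all eight PERC criteria met"
    return AlgorithmDecision(record.patient_id, "perc", verdict, clause,
                             None, record.d_dimer, None)


def peged_algorithm(record: PatientRecord, config: TriageConfig = TriageConfig()) -> AlgorithmDecision:
    """Graduated D-dimer by C-PTP: low & <1000, moderate & <500, high -> imaging."""
    cat = _cptp(record, config)
    if cat is Cptp.LOW:
        cutoff: Optional[float] = config.d_dimer_high_cutoff
    elif cat is Cptp.MODERATE:
        cutoff = config.d_dimer_standard_cutoff
    else:
        cutoff = None
    if cutoff is not None and record.d_dimer < cutoff:
        clause = f"C-PTP {cat.value} and D-dimer {record.d_dimer:g} < {cutoff:g} ng/ml"
        verdict = Verdict.RULE_OUT
    elif cutoff is None:
        clause = "C-PTP high: imaging regardless of D-dimer"
        verdict = Verdict.IMAGING_REQUIRED
    else:
        clause = f"C-PTP {cat.value} but D-dimer {record.d_dimer:g} >= {cutoff:g} ng/ml"
        verdict = Verdict.IMAGING_REQUIRED
    return AlgorithmDecision(record.patient_id, "peged", verdict, clause,
                             cat.value, record.d_dimer, cutoff)


ALGORITHMS: Dict[str, Callable[[PatientRecord, TriageConfig], AlgorithmDecision]] = {
    "standard": standard_algorithm,
    "age_adjusted": age_adjusted_algorithm,
    "years": years_algorithm,
    "perc": perc_algorithm,
    "peged": peged_algorithm,
}


def run_all(
    cohort: CohortTable,
    config: TriageConfig = TriageConfig(),
    algorithms: Optional[Sequence[str]] = None,
) -> Dict[str, Dict[str, AlgorithmDecision]]:
    """Apply the requested engines to every patient.

    Returns ``{algorithm: {patient_id: AlgorithmDecision}}``, one decision
    per (patient, algorithm) pair.
    """
    names = list(ALGORITHMS) if algorithms is None else list(algorithms)
    unknown = [n for n in names if n not in ALGORITHMS]
    if unknown:
        raise ValueError(
            f"unknown algorithm(s) {unknown}; valid names: {sorted(ALGORITHMS)}"
        )
    out: Dict[str, Dict[str, AlgorithmDecision]] = {}
    for name in names:
        engine = ALGORITHMS[name]
        out[name] = {rec.patient_id: engine(rec, config) for rec in cohort}
    return out


def decisions_to_frame(decisions: Dict[str, Dict[str, AlgorithmDecision]]) -> pd.DataFrame:
    """Flatten a decision table to a tidy DataFrame (one row per decision)."""
    rows = []
    for algorithm, per_patient in decisions.items():
        for decision in per_patient.values():
            rows.append({
                "patient_id": decision.patient_id,
                "algorithm": algorithm,
                "verdict": decision.verdict.value,
                "fired_clause": decision.fired_clause,
                "cptp_category": decision.cptp_category,
                "d_dimer": decision.d_dimer,
                "threshold_applied": decision.threshold_applied,
            })
    return pd.DataFrame(rows)
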