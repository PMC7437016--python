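"""Wells score and clinical pretest probability (C-PTP) categories.

The Wells score is a weighted sum of seven clinical items: signs of DVT,
"PE is the most likely diagnosis", tachycardia (HR > 100), recent
immobilization or surgery, prior VTE, hemoptysis, and active cancer.  The
canonical weight vector is (3, 3, 1.5, 1.5, 1.5, 1, 1), giving scores on a
half-point lattice in [0, 12.5].

Two categorical readings of the score are used by the triage algorithms:

* three-level C-PTP (low / moderate / high), with two named cut-point
  presets — ``"peged-trial"`` (low <= 4.0, moderate 4.5-6.0, high >= 6.5;
  the scheme of the graduated-D-dimer trial, the default) and
  ``"traditional"`` (low < 2, moderate 2-6, high > 6);
* two-level (PE likely / PE unlikely), likely iff score > 4.0 (strict).

Scores live on an exact 0.5-point lattice so category boundaries need no
floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .records import PatientRecord

__all__ = [
    "WellsWeights",
    "CptpScheme",
    "Cptp",
    "TwoLevelCptp",
    "compute_wells_score",
    "classify_three_level",
    "classify_two_level",
    "CPTP_SCHEME_PRESETS",
]


class Cptp(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class TwoLevelCptp(str, Enum):
    PE_LIKELY = "pe_likely"
    PE_UNLIKELY = "pe_unlikely"


@dataclass(frozen=True)
class WellsWeights:
    """Item weights of the Wells score (all non-negative points)."""

    dvt_signs_pts: float = 3.0
    pe_most_likely_pts: float = 3.0
    tachycardia_pts: float = 1.5
    immobilization_or_surgery_pts: float = 1.5
    history_vte_pts: float = 1.5
    hemoptysis_pts: float = 1.0
    cancer_pts: float = 1.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"Wells weight {name} must be >= 0, got {value}")

    @property
    def total(self) -> float:
        return sum(self.__dict__.values())


@dataclass(frozen=True)
class CptpScheme:
    """Cut-points partitioning the Wells score into C-PTP categories.

    ``low_max`` / ``moderate_max`` are inclusive upper bounds of the low
    and moderate bands; ``two_level_likely_min`` is the exclusive lower
    bound for "PE likely".
    """

    low_max: float = 4.0
    moderate_max: float = 6.0
    two_level_likely_min: float = 4.0
    name: str = "peged-trial"

    def __post_init__(self):
        if not (0 < self.low_max < self.moderate_max):
            raise ValueError(
                f"require 0 < low_max < moderate_max, got {self.low_max}, {self.moderate_max}"
            )


CPTP_SCHEME_PRESETS = {
    "peged-trial": CptpScheme(low_max=4.0, moderate_max=6.0, two_level_likely_min=4.0,
                              name="peged-trial"),
    "traditional": CptpScheme(low_max=1.5, moderate_max=6.0, two_level_likely_min=4.0,
                              name="traditional"),
}


def compute_wells_score(record: PatientRecord, weights: WellsWeights = WellsWeights()) -> float:
    """Sum the weights of the firing Wells items.

    The immobilization-or-surgery item fires if either
    ``recent_immobilization`` or ``recent_surgery`` is true; the
    tachycardia item fires if heart rate exceeds 100 beats/min (strict).
    """
    score = 0.0
    if record.dvt_signs:
        score += weights.dvt_signs_pts
    if record.pe_most_likely:
        score += weights.pe_most_likely_pts
    if record.heart_rate > 100:
        score += weights.tachycardia_pts
    if record.recent_immobilization or record.recent_surgery:
        score += weights.immobilization_or_surgery_pts
    if record.history_vte:
        score += weights.history_vte_pts
    if record.hemoptysis:
        score += weights.hemoptysis_pts
    if record.active_cancer:
        score += weights.cancer_pts
    return score


def classify_three_level(score: float, scheme: CptpScheme = CptpScheme()) -> Cptp:
    """Map a Wells score to low / moderate / high C-PTP."""
    if score < 0:
        raise ValueError(f"Wells score must be >= 0, got {score}")
    if score <= scheme.low_max:
        return Cptp.LOW
    if score <= scheme.moderate_max:
        return Cptp.MODERATE
    return Cptp.HIGH


def classify_two_level(score: float, scheme: CptpScheme = CptpScheme()) -> TwoLevelCptp:
    """Dichotomized Wells: PE likely iff score strictly exceeds the boundary."""
    if score < 0:
        raise ValueError(f"Wells score must be >= 0, got {score}")
    if score > scheme.two_level_likely_min:
        return TwoLevelCptp.PE_LIKELY
    return TwoLevelCptp.PE_UNLIKELY
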