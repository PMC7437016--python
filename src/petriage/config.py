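"""Run configuration: thresholds, C-PTP scheme presets and simulation
targets, loadable from YAML or JSON.

Recognised top-level keys (all optional):

``wells_weights``
    mapping of Wells item weights (``dvt_signs_pts`` ...).
``cptp_scheme``
    preset name (``"peged-trial"`` or ``"traditional"``) or an explicit
    mapping with ``low_max`` / ``moderate_max`` / ``two_level_likely_min``.
``triage``
    D-dimer cutoffs, PERC limits and engine flags (field names of
    :class:`~petriage.rules.TriageConfig`).
``simulation``
    :class:`~petriage.simulate.CohortSimConfig` fields; the per-group
    blocks ``pe_absent`` / ``pe_present`` take ``GroupSpec`` fields.
``rounding``
    ``"published"`` (default) or ``"exact"``.
``d_dimer_in_ug_ml``
    declare input D-dimer in ug/ml (x1000 on ingest; default false).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .rules import TriageConfig
from .simulate import CohortSimConfig, GroupSpec
from .wells import CPTP_SCHEME_PRESETS, CptpScheme, WellsWeights

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    triage: TriageConfig = field(default_factory=TriageConfig)
    simulation: Optional[CohortSimConfig] = None
    rounding: str = "published"
    d_dimer_in_ug_ml: bool = False
    output_dir: Path = Path(".")
    log_level: str = "INFO"


def _build_scheme(raw) -> CptpScheme:
    if raw is None:
        return CptpScheme()
    if isinstance(raw, str):
        try:
            return CPTP_SCHEME_PRESETS[raw]
        except KeyError:
            raise ValueError(
                f"unknown C-PTP scheme preset {raw!r}; "
                f"available: {sorted(CPTP_SCHEME_PRESETS)}") from None
    return CptpScheme(**raw)


def _dataclass_from(cls, raw: dict, **overrides):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**{**raw, **overrides})


def load_run_config(path=None, data: Optional[dict] = None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML/JSON file or a raw mapping."""
    if data is None:
        if path is None:
            return RunConfig()
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        data = data or {}
    weights = _dataclass_from(WellsWeights, data.get("wells_weights", {}) or {})
    scheme = _build_scheme(data.get("cptp_scheme"))
    triage = _dataclass_from(TriageConfig, data.get("triage", {}) or {},
                             wells=weights, scheme=scheme)
    simulation = None
    if "simulation" in data and data["simulation"] is not None:
        sim_raw = dict(data["simulation"])
        groups = {}
        for gname in ("pe_absent", "pe_present"):
            if gname in sim_raw:
                base = getattr(CohortSimConfig(), gname)
                groups[gname] = dataclasses.replace(base, **sim_raw.pop(gname))
        simulation = _dataclass_from(CohortSimConfig, sim_raw, **groups)
    rounding = data.get("rounding", "published")
    if rounding not in ("published", "exact"):
        raise ValueError(f"unknown rounding convention {rounding!r}")
    return RunConfig(
        triage=triage,
        simulation=simulation,
        rounding=rounding,
        d_dimer_in_ug_ml=bool(data.get("d_dimer_in_ug_ml", False)),
        output_dir=Path(data.get("output_dir", ".")),
        log_level=str(data.get("log_level", "INFO")),
    )
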