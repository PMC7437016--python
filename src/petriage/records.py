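"""Patient records and cohort tables.

One :class:`PatientRecord` carries the clinical variables consumed by the
five PE-likelihood algorithms (Wells items, PERC items, D-dimer, vitals)
plus an optional reference-standard label ``confirmed_pe`` adjudicated by
chest imaging.  A :class:`CohortTable` is an ordered collection of records
with unique patient ids, read from / written to plain CSV.

Validation is total: every CSV row is either accepted or rejected with an
error naming the row and the offending column; out-of-range values are
never silently coerced.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "PatientRecord",
    "CohortTable",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "BOOLEAN_FIELDS",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]


class CohortSchemaError(ValueError):
    """A required column is missing from a cohort file."""


class CohortValidationError(ValueError):
    """A cell or record violates the cohort schema (row-level)."""


#: Boolean clinical items (Wells + PERC + YEARS inputs).
BOOLEAN_FIELDS = (
    "dvt_signs",
    "pe_most_likely",
    "hemoptysis",
    "recent_immobilization",
    "recent_surgery",
    "recent_trauma",
    "history_vte",
    "active_cancer",
    "oral_hormone_use",
    "unilateral_leg_swelling",
)

REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "heart_rate",
    "sao2",
    "d_dimer",
) + BOOLEAN_FIELDS

OPTIONAL_COLUMNS = ("bode_index", "confirmed_pe")

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_bool(raw: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValueError(f"cannot interpret {raw!r} as a boolean (use 1/0, true/false, yes/no)")


class PatientRecord(BaseModel):
    """One patient's clinical variables and optional PE reference standard.

    Units: ``age`` years, ``heart_rate`` beats/min, ``sao2`` percent,
    ``d_dimer`` ng/ml.  ``confirmed_pe`` is the imaging-adjudicated truth
    label; it may be absent for prospective (prediction-only) use but must
    be present on every record entering accuracy evaluation.
    ``bode_index`` is a passthrough severity score used by no algorithm.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age: int
    heart_rate: float
    sao2: float
    d_dimer: float
    dvt_signs: bool
    pe_most_likely: bool
    hemoptysis: bool
    recent_immobilization: bool
    recent_surgery: bool
    recent_trauma: bool
    history_vte: bool
    active_cancer: bool
    oral_hormone_use: bool
    unilateral_leg_swelling: bool
    bode_index: Optional[float] = None
    confirmed_pe: Optional[bool] = None

    @field_validator("age")
    @classmethod
    def _age_nonnegative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("age must be >= 0 years")
        return v

    @field_validator("heart_rate")
    @classmethod
    def _hr_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("heart_rate must be > 0 beats/min")
        return v

    @field_validator("sao2")
    @classmethod
    def _sao2_in_range(cls, v: float) -> float:
        if not (0.0 <= v <= 100.0):
            raise ValueError("sao2 must lie in [0, 100] percent")
        return v

    @field_validator("d_dimer")
    @classmethod
    def _ddimer_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("d_dimer must be >= 0 ng/ml")
        return v


class CohortTable:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    def __init__(self, records: Sequence[PatientRecord], source: str = "memory"):
        records = list(records)
        seen: set[str] = set()
        for rec in records:
            if rec.patient_id in seen:
                raise CohortValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
        self.records: list[PatientRecord] = records
        self.source = source

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.records == other.records

    def to_dataframe(self) -> pd.DataFrame:
        """Cohort as a pandas DataFrame, one row per patient, file order."""
        return pd.DataFrame([r.model_dump() for r in self.records])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str = "dataframe") -> "CohortTable":
        records = []
        for row in df.to_dict(orient="records"):
            clean = {k: v for k, v in row.items() if not pd.isna(v)}
            records.append(PatientRecord(**clean))
        return cls(records, source=source)

    def require_truth(self) -> None:
        """Raise unless every record carries a confirmed_pe label."""
        missing = [r.patient_id for r in self.records if r.confirmed_pe is None]
        if missing:
            raise CohortValidationError(
                f"confirmed_pe missing for {len(missing)} patient(s), "
                f"first: {missing[0]!r}; truth labels are required for evaluation"
            )


def _format_number(value: float) -> str:
    # repr round-trips floats exactly; integers stay integral
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return repr(value)


def read_cohort(path, *, d_dimer_in_ug_ml: bool = False, dialect: str = "excel") -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Column names are matched case-insensitively.  Booleans accept
    1/0, true/false and yes/no.  ``d_dimer_in_ug_ml=True`` declares the
    D-dimer column in µg/ml and multiplies by 1000 on ingest (the package
    works in ng/ml throughout).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, dialect=dialect)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, header row required")
        header_map = {name.strip().lower(): name for name in reader.fieldnames}
        for col in REQUIRED_COLUMNS:
            if col not in header_map:
                raise CohortSchemaError(f"{path}: missing required column {col!r}")

        records: list[PatientRecord] = []
        for rownum, row in enumerate(reader, start=2):  # header is line 1
            fields: dict = {}
            for col in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
                src = header_map.get(col)
                raw = row.get(src, "") if src else ""
                raw = "" if raw is None else raw.strip()
                if raw == "":
                    if col in REQUIRED_COLUMNS:
                        raise CohortValidationError(
                            f"{path} row {rownum}: empty value in required column {col!r}"
                        )
                    continue
                try:
                    if col in BOOLEAN_FIELDS or col == "confirmed_pe":
                        fields[col] = _parse_bool(raw)
                    elif col == "patient_id":
                        fields[col] = raw
                    elif col == "age":
                        fields[col] = int(float(raw))
                    else:
                        fields[col] = float(raw)
                except ValueError as exc:
                    raise CohortValidationError(
                        f"{path} row {rownum}, column {col!r}: {exc}"
                    ) from exc
            if d_dimer_in_ug_ml:
                fields["d_dimer"] = fields["d_dimer"] * 1000.0
            try:
                records.append(PatientRecord(**fields))
            except Exception as exc:
                raise CohortValidationError(f"{path} row {rownum}: {exc}") from exc

    return CohortTable(records, source=str(path))


def write_cohort(cohort: CohortTable, path) -> Path:
    """Write a cohort to CSV such that ``read_cohort`` round-trips exactly.

    Booleans serialize as true/false; absent optional fields as empty cells.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    path = Path(path)
    columns = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(columns)
    for rec in cohort:
        row = []
        for col in columns:
            value = getattr(rec, col)
            if value is None:
                row.append("")
            elif isinstance(value, bool):
                row.append("true" if value else "false")
            elif col == "patient_id":
                row.append(value)
            elif col == "age":
                row.append(str(value))
            else:
                row.append(_format_number(value))
        writer.writerow(row)
    path.write_text(buffer.getvalue(), encoding="utf-8")
    return path
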