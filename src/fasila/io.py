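"""Cohort CSV reading and writing.

One header row; columns named exactly as the patient-record fields; enums as
lowercase strings; booleans as ``true``/``false``; missing values as empty
cells.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scores import (
    FastResult,
    Management,
    Mechanism,
    PatientRecord,
    ScoreDomainError,
    Sex,
)

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "records_to_dataframe",
    "dataframe_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(PatientRecord)
)

_ENUM_FIELDS = {
    "sex": Sex,
    "mechanism": Mechanism,
    "fast": FastResult,
    "management": Management,
}
_BOOL_FIELDS = ("transfused", "mtp", "laparotomy", "mortality")
_INT_FIELDS = ("gcs", "iss", "abdominal_ais", "sofa", "blood_units")
_OPTIONAL_INT_FIELDS = ("pelvic_ais",)
_FLOAT_FIELDS = ("age", "hr", "sbp", "dbp", "lactate", "rts", "triss",
                 "icu_los", "hospital_los")
_OPTIONAL_FLOAT_FIELDS = ("fibrinogen",)


class SchemaError(ValueError):
    """Input does not conform to the cohort CSV schema."""


def records_to_dataframe(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        for name, enum_cls in _ENUM_FIELDS.items():
            row[name] = enum_cls(row[name]).value
        for name in _BOOL_FIELDS:
            row[name] = "true" if row[name] else "false"
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def _parse_bool(value, column: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise SchemaError(f"row {row}, column '{column}': invalid boolean {value!r}")


def dataframe_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Parse a cohort data frame into validated patient records."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing cohort columns: {sorted(missing)}")
    records = []
    for i, raw in enumerate(df.to_dict("records")):
        kw: dict = {"patient_id": str(raw["patient_id"])}
        for name, enum_cls in _ENUM_FIELDS.items():
            try:
                kw[name] = enum_cls(str(raw[name]).strip().lower())
            except ValueError as exc:
                raise SchemaError(
                    f"row {i}, column '{name}': unknown value {raw[name]!r}"
                ) from exc
        for name in _BOOL_FIELDS:
            kw[name] = _parse_bool(raw[name], name, i)
        for group, caster, optional in (
            (_INT_FIELDS, int, False),
            (_OPTIONAL_INT_FIELDS, int, True),
            (_FLOAT_FIELDS, float, False),
            (_OPTIONAL_FLOAT_FIELDS, float, True),
        ):
            for name in group:
                value = raw[name]
                is_missing = value is None or (
                    isinstance(value, float) and np.isnan(value)
                ) or str(value).strip() == ""
                if is_missing:
                    if optional:
                        kw[name] = None
                        continue
                    raise SchemaError(f"row {i}, column '{name}': missing value")
                try:
                    kw[name] = caster(float(value))
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"row {i}, column '{name}': invalid number {value!r}"
                    ) from exc
        try:
            records.append(PatientRecord(**kw))
        except ScoreDomainError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return records


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the schema.

    Returns the data frame (with validated types); use
    :func:`dataframe_to_records` for record objects.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    dataframe_to_records(df)  # validation pass
    return df


def write_cohort_csv(records: Sequence[PatientRecord] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    df.to_csv(path, index=False, lineterminator="\n")
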