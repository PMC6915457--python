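"""CSV readers and writers for measurement sequences and rosters.

Measurement files are long format, one row per (subject, slot):

    subject_id,slot,role,sbp,dbp,hr

Roster files carry one row per subject:

    subject_id,sex,age,height_cm,weight_kg,arm_circumference_mm,arm,flags

``flags`` is a semicolon-separated set (may be empty).  Files are UTF-8,
comma-delimited, header required.  Readers validate everything up front
and raise :class:`StudyFormatError` naming the offending line, so a bad
file never reaches the grader.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import (
    SLOT_LABELS,
    ReadingTriplet,
    SequenceRecord,
    SubjectProfile,
    role_for,
    validate_sequence,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "ROSTER_COLUMNS",
    "StudyFormatError",
    "read_measurements",
    "read_roster",
    "read_study",
    "write_measurements",
    "write_roster",
]

MEASUREMENT_COLUMNS = ("subject_id", "slot", "role", "sbp", "dbp", "hr")
ROSTER_COLUMNS = (
    "subject_id", "sex", "age", "height_cm", "weight_kg",
    "arm_circumference_mm", "arm", "flags",
)


class StudyFormatError(ValueError):
    """A study file violates the expected dialect or the data invariants."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyFormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_measurements(path) -> list[SequenceRecord]:
    """Parse and validate a long-format measurement file.

    Returns one fully validated record per subject, in order of first
    appearance.  Any structural problem (unknown slot label, role
    inconsistent with the slot, non-integer reading, duplicate or
    missing slot) is a hard error naming the file line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    problems: list[str] = []
    rows_by_subject: dict[str, dict[str, ReadingTriplet]] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sid = row["subject_id"].strip()
        slot = row["slot"].strip()
        if slot not in SLOT_LABELS:
            problems.append(f"line {line}: unknown slot label {slot!r}")
            continue
        if row["role"].strip() != role_for(slot):
            problems.append(
                f"line {line}: role {row['role']!r} inconsistent with slot {slot} "
                f"(expected {role_for(slot)!r})"
            )
        values = {}
        for col in ("sbp", "dbp", "hr"):
            raw = row[col].strip()
            try:
                values[col] = int(raw)
            except ValueError:
                problems.append(f"line {line}: non-integer {col} reading {raw!r}")
        if len(values) != 3:
            continue
        if sid not in rows_by_subject:
            rows_by_subject[sid] = {}
            order.append(sid)
        if slot in rows_by_subject[sid]:
            problems.append(f"line {line}: duplicate slot {slot} for subject {sid}")
            continue
        rows_by_subject[sid][slot] = ReadingTriplet(**values)
    if problems:
        raise StudyFormatError(f"{path}: " + "; ".join(problems))
    records = [SequenceRecord(sid, rows_by_subject[sid]) for sid in order]
    for record in records:
        violations = validate_sequence(record)
        if violations:
            raise StudyFormatError(
                f"{path}: " + "; ".join(str(v) for v in violations)
            )
    return records


def read_roster(path) -> list[SubjectProfile]:
    """Parse a roster CSV into subject profiles."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ROSTER_COLUMNS, path)
    profiles = []
    for idx, row in df.iterrows():
        line = idx + 2
        flags = frozenset(f for f in row["flags"].split(";") if f)
        try:
            profiles.append(
                SubjectProfile(
                    subject_id=row["subject_id"].strip(),
                    sex=row["sex"].strip(),
                    age=float(row["age"]),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    arm_circumference_mm=float(row["arm_circumference_mm"]),
                    arm=row["arm"].strip(),
                    flags=flags,
                )
            )
        except ValueError as exc:
            raise StudyFormatError(f"{path}: line {line}: {exc}") from exc
    return profiles


def read_study(measurements_path, roster_path) -> tuple[list[SequenceRecord], list[SubjectProfile]]:
    """Read and cross-validate the measurement file and roster together."""
    records = read_measurements(measurements_path)
    roster = read_roster(roster_path)
    return records, roster


def write_measurements(records: Sequence[SequenceRecord], path) -> None:
    """Write records in the long CSV dialect (slots in schedule order)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for record in records:
            for slot in SLOT_LABELS:
                r = record.reading(slot)
                writer.writerow(
                    [record.subject_id, slot, role_for(slot), r.sbp, r.dbp, r.hr]
                )


def write_roster(profiles: Sequence[SubjectProfile], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for p in profiles:
            writer.writerow(
                [
                    p.subject_id, p.sex, repr(p.age), repr(p.height_cm),
                    repr(p.weight_kg), repr(p.arm_circumference_mm), p.arm,
                    ";".join(sorted(p.flags)),
                ]
            )
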