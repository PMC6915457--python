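"""Shared builders for validation-session fixtures.

All fixture data is constructed programmatically; a "record" here is a
subject's nine-slot schedule (BPA..BP7) built from a constant baseline
triplet with optional per-slot overrides or a constant test-device
offset.
"""

from __future__ import annotations

import numpy as np
import pytest

from eshval.model import (
    SLOT_LABELS,
    TEST_SLOTS,
    ReadingTriplet,
    SequenceRecord,
    SubjectProfile,
)
from eshval.pairing import PairedDifference


def make_record(
    subject_id: str = "S001",
    base: tuple[int, int, int] = (120, 80, 70),
    overrides: dict[str, tuple[int, int, int]] | None = None,
    test_offset: tuple[int, int, int] = (0, 0, 0),
) -> SequenceRecord:
    """Nine-slot record: constant baseline, test slots shifted by
    ``test_offset``, then per-slot ``overrides`` applied."""
    slots = {}
    for slot in SLOT_LABELS:
        sbp, dbp, hr = base
        if slot in TEST_SLOTS:
            sbp, dbp, hr = sbp + test_offset[0], dbp + test_offset[1], hr + test_offset[2]
        if overrides and slot in overrides:
            sbp, dbp, hr = overrides[slot]
        slots[slot] = ReadingTriplet(sbp=sbp, dbp=dbp, hr=hr)
    return SequenceRecord(subject_id=subject_id, slots=slots)


def random_record(rng: np.random.Generator, subject_id: str = "S001") -> SequenceRecord:
    """A valid record with independently jittered readings per slot."""
    slots = {}
    for slot in SLOT_LABELS:
        sbp = int(rng.integers(100, 180))
        dbp = int(rng.integers(50, min(sbp - 5, 110)))
        hr = int(rng.integers(50, 110))
        slots[slot] = ReadingTriplet(sbp=sbp, dbp=dbp, hr=hr)
    return SequenceRecord(subject_id=subject_id, slots=slots)


def diffs_with_abs(
    abs_values, parameter: str = "sbp", per_subject: int = 3
) -> list[PairedDifference]:
    """Paired differences realizing given absolute magnitudes, grouped
    into subjects of ``per_subject`` comparisons each."""
    out = []
    for i, a in enumerate(abs_values):
        out.append(
            PairedDifference(
                subject_id=f"P{i // per_subject + 1:03d}",
                comparison_index=i % per_subject + 1,
                parameter=parameter,
                test_value=100 + int(a),
                reference_value=100,
                flank="preceding",
            )
        )
    return out


def make_profile(
    subject_id: str = "S001",
    sex: str = "male",
    age: float = 60.0,
    flags=(),
) -> SubjectProfile:
    return SubjectProfile(
        subject_id=subject_id,
        sex=sex,
        age=age,
        height_cm=170.0,
        weight_kg=75.0,
        arm_circumference_mm=280.0,
        flags=frozenset(flags),
    )


@pytest.fixture
def identity_dataset() -> list[SequenceRecord]:
    """33 records where every test reading equals its references."""
    return [make_record(f"S{i:03d}") for i in range(1, 34)]
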