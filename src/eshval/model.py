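"""Domain model for ESH-IP2 nine-reading device-validation sessions.

The 2010 revision of the European Society of Hypertension International
Protocol (ESH-IP2) validates an automated blood-pressure monitor against a
reference device on 33 adult subjects.  Each subject contributes nine
consecutive cuff readings taken on alternating devices:

====  =========  ======================================
slot  device     purpose
====  =========  ======================================
BPA   reference  entry reading (never graded)
BPB   test       device-detection reading (never graded)
BP1   reference  graded schedule
BP2   test       graded schedule
BP3   reference  graded schedule
BP4   test       graded schedule
BP5   reference  graded schedule
BP6   test       graded schedule
BP7   reference  graded schedule
====  =========  ======================================

Each reading records systolic pressure (SBP) and diastolic pressure (DBP)
in mm Hg and heart rate (HR) in beats per minute, all as displayed
integers.  The role of a slot is a pure function of its label; the
grading pipeline refuses to consume BPA/BPB.

This module owns the value types (readings, sequences, subject profiles,
grading-requirement constants), sequence validation, and cohort
screening.  Everything downstream (pairing, grading, agreement) builds on
these types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "SLOT_LABELS",
    "REFERENCE_SLOTS",
    "TEST_SLOTS",
    "GRADED_TEST_SLOTS",
    "PARAMETERS",
    "PARAMETER_LABELS",
    "SBP_RANGE",
    "DBP_RANGE",
    "HR_RANGE",
    "role_for",
    "ReadingTriplet",
    "SequenceRecord",
    "SubjectProfile",
    "BandThresholds",
    "BP_BANDS",
    "HR_BANDS",
    "Part1Requirements",
    "Part2Requirements",
    "Violation",
    "validate_sequence",
    "ScreeningReport",
    "cohort_screen",
]

#: All nine slot labels, in chronological acquisition order.
SLOT_LABELS: tuple[str, ...] = (
    "BPA", "BPB", "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)

REFERENCE_SLOTS = frozenset({"BPA", "BP1", "BP3", "BP5", "BP7"})
TEST_SLOTS = frozenset({"BPB", "BP2", "BP4", "BP6"})

#: Test-device slots that enter grading, in order (comparisons 1..3).
GRADED_TEST_SLOTS: tuple[str, ...] = ("BP2", "BP4", "BP6")

#: Measured parameters, as attribute names on :class:`ReadingTriplet`.
PARAMETERS: tuple[str, ...] = ("sbp", "dbp", "hr")

PARAMETER_LABELS: Mapping[str, str] = {
    "sbp": "Systolic blood pressure",
    "dbp": "Diastolic blood pressure",
    "hr": "Heart rate",
}

# Physiologically plausible display ranges; readings outside are data errors.
SBP_RANGE: tuple[int, int] = (40, 300)
DBP_RANGE: tuple[int, int] = (20, 200)
HR_RANGE: tuple[int, int] = (20, 250)

_RANGES: Mapping[str, tuple[int, int]] = {
    "sbp": SBP_RANGE,
    "dbp": DBP_RANGE,
    "hr": HR_RANGE,
}


def role_for(slot: str) -> str:
    """Return ``"reference"`` or ``"test"`` for a slot label.

    The role is fixed by the protocol schedule and is not stored per
    record.  Raises :class:`ValueError` for an unknown label.
    """
    if slot in REFERENCE_SLOTS:
        return "reference"
    if slot in TEST_SLOTS:
        return "test"
    raise ValueError(f"unknown slot label {slot!r}")


@dataclass(frozen=True)
class ReadingTriplet:
    """One cuff reading: SBP and DBP in mm Hg, HR in bpm.

    Values are stored as the integers the devices display; differences
    computed downstream are therefore exact integers and band membership
    is never subject to floating-point edge ambiguity.
    """

    sbp: int
    dbp: int
    hr: int

    def value(self, parameter: str) -> int:
        if parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)


@dataclass(frozen=True)
class SequenceRecord:
    """A subject's nine-slot reading schedule.

    ``slots`` maps slot label to reading.  Roles are implied by the
    label (see :func:`role_for`); a record is graded only after
    :func:`validate_sequence` returns no violations.
    """

    subject_id: str
    slots: Mapping[str, ReadingTriplet]

    def reading(self, slot: str) -> ReadingTriplet:
        return self.slots[slot]


@dataclass(frozen=True)
class SubjectProfile:
    """Roster entry used for cohort screening and the synthetic cohort.

    ``bmi`` may be omitted, in which case it is derived as
    weight / (height/100)**2; a supplied value disagreeing with the
    derived one by more than 0.5 kg/m^2 is rejected.  ``flags`` holds
    exclusion conditions (``arrhythmia``, ``circulatory_problem``,
    ``pregnancy``, ``device_failure``); any flag excludes the subject.
    """

    subject_id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    arm_circumference_mm: float
    arm: str = "right"
    flags: frozenset[str] = frozenset()
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.arm not in ("left", "right"):
            raise ValueError(f"arm must be 'left' or 'right', got {self.arm!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        derived = self.weight_kg / (self.height_cm / 100.0) ** 2
        if self.bmi is None:
            object.__setattr__(self, "bmi", derived)
        elif abs(self.bmi - derived) > 0.5:
            raise ValueError(
                f"subject {self.subject_id}: bmi {self.bmi:.2f} inconsistent "
                f"with weight/height (derived {derived:.2f})"
            )


@dataclass(frozen=True)
class BandThresholds:
    """Three cumulative absolute-difference cutoffs for one parameter.

    Band membership downstream is inclusive: a difference of exactly
    ``cutoffs[i]`` counts as within band *i*.
    """

    cutoffs: tuple[int, int, int]
    units: str

    def __post_init__(self) -> None:
        if len(self.cutoffs) != 3:
            raise ValueError("exactly three band cutoffs required")
        if not (0 <= self.cutoffs[0] < self.cutoffs[1] < self.cutoffs[2]):
            raise ValueError(f"cutoffs must be ascending and non-negative: {self.cutoffs}")

    @property
    def first(self) -> int:
        """The first-band cutoff, also the per-subject Part 2 criterion."""
        return self.cutoffs[0]


#: Blood-pressure bands: within 5, 10, 15 mm Hg.
BP_BANDS = BandThresholds((5, 10, 15), "mm Hg")
#: Heart-rate bands: within 3, 5, 8 bpm.
HR_BANDS = BandThresholds((3, 5, 8), "bpm")


@dataclass(frozen=True)
class Part1Requirements:
    """Per-measurement pass requirements: of ``n_comparisons``, at least
    two bands must reach their ``two_of`` count and every band its
    ``all_of`` count."""

    n_comparisons: int = 99
    two_of: tuple[int, int, int] = (73, 87, 96)
    all_of: tuple[int, int, int] = (65, 81, 93)

    def __post_init__(self) -> None:
        if len(self.two_of) != 3 or len(self.all_of) != 3:
            raise ValueError("two_of and all_of each need three counts")
        for a, t in zip(self.all_of, self.two_of):
            if a > t:
                raise ValueError(f"all_of {a} exceeds two_of {t}")
        if max(*self.two_of, *self.all_of) > self.n_comparisons:
            raise ValueError("requirement counts exceed n_comparisons")


@dataclass(frozen=True)
class Part2Requirements:
    """Per-subject pass requirements: of ``n_subjects``, at least
    ``min_subjects_2of3`` must have two of their three differences
    within the first band, and at most ``max_subjects_0of3`` may have
    none within it."""

    n_subjects: int = 33
    min_subjects_2of3: int = 24
    max_subjects_0of3: int = 3

    def __post_init__(self) -> None:
        if self.min_subjects_2of3 + self.max_subjects_0of3 > self.n_subjects:
            raise ValueError("part 2 requirements infeasible for n_subjects")


@dataclass(frozen=True)
class Violation:
    """One data-quality finding: the rule broken and where."""

    rule: str
    message: str
    subject_id: str | None = None
    slot: str | None = None
    line: int | None = None

    def __str__(self) -> str:
        where = []
        if self.subject_id is not None:
            where.append(f"subject {self.subject_id}")
        if self.slot is not None:
            where.append(f"slot {self.slot}")
        if self.line is not None:
            where.append(f"line {self.line}")
        prefix = f"[{', '.join(where)}] " if where else ""
        return f"{prefix}{self.rule}: {self.message}"


def _reading_violations(subject_id: str, slot: str, r: ReadingTriplet) -> list[Violation]:
    out: list[Violation] = []
    for param in PARAMETERS:
        lo, hi = _RANGES[param]
        v = r.value(param)
        if not isinstance(v, (int,)) or isinstance(v, bool):
            out.append(Violation("integer-reading", f"{param}={v!r} is not an integer",
                                 subject_id, slot))
            continue
        if not lo <= v <= hi:
            out.append(Violation("range", f"{param}={v} outside [{lo}, {hi}]",
                                 subject_id, slot))
    if isinstance(r.sbp, int) and isinstance(r.dbp, int) and r.sbp <= r.dbp:
        out.append(Violation("sbp > dbp", f"sbp={r.sbp} not greater than dbp={r.dbp}",
                             subject_id, slot))
    return out


def validate_sequence(record: SequenceRecord) -> list[Violation]:
    """Check a record against the nine-slot schedule invariants.

    Returns an empty list iff the record is gradable.  Violations are
    data, not exceptions: each names the slot and the rule broken
    (missing or unknown slot, non-integer or out-of-range reading,
    sbp not exceeding dbp).
    """
    out: list[Violation] = []
    sid = record.subject_id
    for slot in SLOT_LABELS:
        if slot not in record.slots:
            out.append(Violation("missing-slot", f"slot {slot} absent", sid, slot))
    for slot in record.slots:
        if slot not in SLOT_LABELS:
            out.append(Violation("unknown-slot", f"slot label {slot!r} not in schedule",
                                 sid, slot))
    for slot, reading in record.slots.items():
        if slot in SLOT_LABELS:
            out.extend(_reading_violations(sid, slot, reading))
    return out


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of cohort screening against the inclusion criteria."""

    included_ids: tuple[str, ...]
    excluded: Mapping[str, tuple[str, ...]]  # subject_id -> reasons
    n_male: int
    n_female: int
    passed: bool
    problems: tuple[str, ...]

    @property
    def n_included(self) -> int:
        return len(self.included_ids)


def cohort_screen(
    profiles: Sequence[SubjectProfile],
    *,
    min_included: int = 33,
    min_per_sex: int = 10,
) -> ScreeningReport:
    """Screen a roster against the protocol's inclusion criteria.

    A subject is excluded when younger than 25 years or carrying any
    exclusion flag.  The cohort as a whole passes when at least
    ``min_included`` subjects remain and each sex contributes at least
    ``min_per_sex``.  The function is permutation-invariant apart from
    the order of ``included_ids``, which follows the roster.
    """
    if not profiles:
        raise ValueError("empty roster")
    included: list[str] = []
    excluded: dict[str, tuple[str, ...]] = {}
    n_male = n_female = 0
    for p in profiles:
        reasons: list[str] = []
        if p.age < 25:
            reasons.append("age below 25")
        reasons.extend(sorted(p.flags))
        if reasons:
            excluded[p.subject_id] = tuple(reasons)
        else:
            included.append(p.subject_id)
            if p.sex == "male":
                n_male += 1
            else:
                n_female += 1
    problems: list[str] = []
    if len(included) < min_included:
        problems.append(f"only {len(included)} subjects included (need {min_included})")
    if n_male < min_per_sex:
        problems.append(f"only {n_male} male subjects (need {min_per_sex})")
    if n_female < min_per_sex:
        problems.append(f"only {n_female} female subjects (need {min_per_sex})")
    return ScreeningReport(
        included_ids=tuple(included),
        excluded=excluded,
        n_male=n_male,
        n_female=n_female,
        passed=not problems,
        problems=tuple(problems),
    )
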