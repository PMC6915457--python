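"""Part 1 / Part 2 / Part 3 grading of paired differences.

Part 1 counts comparisons (normally 99) whose absolute differences fall
within three cumulative bands (5/10/15 mm Hg for pressure, 3/5/8 bpm for
heart rate).  The device passes Part 1 when at least two bands reach
their higher required count (73/87/96) and every band reaches its lower
one (65/81/93).

Part 2 is per subject: of 33 subjects, at least 24 must have two of
their three differences within the first band, and at most 3 may have
none within it.

Part 3 simply requires every constituent Part 1 and Part 2 grade to
pass.  Blood pressure combines SBP and DBP into one Part 3 decision;
heart rate carries its own.

Band membership is inclusive (a difference of exactly 5 mm Hg is
"within 5"); with integer readings this is unambiguous.
"""

from __future__ import annotations

import math
import warnings
from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .agreement import AgreementSummary, difference_summary
from .model import (
    BP_BANDS,
    HR_BANDS,
    BandThresholds,
    Part1Requirements,
    Part2Requirements,
    SequenceRecord,
)
from .pairing import PairedDifference, SelectionMode, all_differences

__all__ = [
    "BandCounts",
    "SubjectBandProfile",
    "BandDetail",
    "Part1Detail",
    "Part2Detail",
    "ParameterGrade",
    "DeviceGradeReport",
    "band_counts",
    "subject_band_profiles",
    "grade_part1",
    "grade_part2",
    "grade_part3",
    "grade_device",
    "part1_requirements_for",
    "part2_requirements_for",
]


@dataclass(frozen=True)
class BandCounts:
    """Cumulative within-band counts out of ``n`` comparisons."""

    n: int
    within: tuple[int, int, int]

    def __post_init__(self) -> None:
        w1, w2, w3 = self.within
        if not (0 <= w1 <= w2 <= w3 <= self.n):
            raise ValueError(
                f"within-band counts must be cumulative and bounded by n: "
                f"{self.within} with n={self.n}"
            )


@dataclass(frozen=True)
class SubjectBandProfile:
    """How many of a subject's three differences fall within the first band."""

    subject_id: str
    n_within_first_band: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_within_first_band <= 3:
            raise ValueError("n_within_first_band must be in 0..3")


@dataclass(frozen=True)
class BandDetail:
    cutoff: int
    achieved: int
    two_of_required: int
    all_of_required: int
    meets_two_of: bool
    meets_all_of: bool


@dataclass(frozen=True)
class Part1Detail:
    passed: bool
    counts: BandCounts
    requirements: Part1Requirements
    bands: tuple[BandDetail, BandDetail, BandDetail]
    n_two_of_met: int


@dataclass(frozen=True)
class Part2Detail:
    passed: bool
    n_subjects: int
    n_with_two_of_three: int
    n_with_zero_of_three: int
    requirements: Part2Requirements


def band_counts(
    differences: Sequence[PairedDifference], thresholds: BandThresholds
) -> BandCounts:
    """Count differences within each cumulative band (inclusive cutoffs)."""
    params = {d.parameter for d in differences}
    if len(params) > 1:
        raise ValueError(f"mixed parameters in one band count: {sorted(params)}")
    absdiffs = [d.abs_difference for d in differences]
    within = tuple(sum(a <= c for a in absdiffs) for c in thresholds.cutoffs)
    return BandCounts(n=len(absdiffs), within=within)  # type: ignore[arg-type]


def subject_band_profiles(
    differences: Sequence[PairedDifference], first_cutoff: int
) -> list[SubjectBandProfile]:
    """Per-subject first-band tallies from a parameter's differences.

    Expects exactly three differences per subject; order of subjects
    follows first appearance.
    """
    counts: "OrderedDict[str, list[int]]" = OrderedDict()
    for d in differences:
        counts.setdefault(d.subject_id, []).append(d.abs_difference)
    profiles = []
    for sid, diffs in counts.items():
        if len(diffs) != 3:
            raise ValueError(f"subject {sid} has {len(diffs)} differences, expected 3")
        profiles.append(
            SubjectBandProfile(sid, sum(a <= first_cutoff for a in diffs))
        )
    return profiles


def grade_part1(
    counts: BandCounts, requirements: Part1Requirements = Part1Requirements()
) -> Part1Detail:
    """Grade the per-measurement stage.

    Passes iff at least two bands reach their ``two_of`` count and all
    three reach their ``all_of`` count.  The number of comparisons must
    match the requirements (normally 99).
    """
    if counts.n != requirements.n_comparisons:
        raise ValueError(
            f"expected {requirements.n_comparisons} comparisons, got {counts.n}"
        )
    bands = []
    for cutoff_index in range(3):
        achieved = counts.within[cutoff_index]
        two_req = requirements.two_of[cutoff_index]
        all_req = requirements.all_of[cutoff_index]
        bands.append(
            BandDetail(
                cutoff=cutoff_index,
                achieved=achieved,
                two_of_required=two_req,
                all_of_required=all_req,
                meets_two_of=achieved >= two_req,
                meets_all_of=achieved >= all_req,
            )
        )
    n_two = sum(b.meets_two_of for b in bands)
    passed = n_two >= 2 and all(b.meets_all_of for b in bands)
    return Part1Detail(
        passed=passed,
        counts=counts,
        requirements=requirements,
        bands=tuple(bands),
        n_two_of_met=n_two,
    )


def grade_part2(
    profiles: Sequence[SubjectBandProfile],
    requirements: Part2Requirements = Part2Requirements(),
) -> Part2Detail:
    """Grade the per-subject stage (>=24 with 2-of-3, <=3 with 0-of-3)."""
    if len(profiles) != requirements.n_subjects:
        raise ValueError(
            f"expected {requirements.n_subjects} subjects, got {len(profiles)}"
        )
    n_two = sum(p.n_within_first_band >= 2 for p in profiles)
    n_zero = sum(p.n_within_first_band == 0 for p in profiles)
    passed = (
        n_two >= requirements.min_subjects_2of3
        and n_zero <= requirements.max_subjects_0of3
    )
    return Part2Detail(
        passed=passed,
        n_subjects=len(profiles),
        n_with_two_of_three=n_two,
        n_with_zero_of_three=n_zero,
        requirements=requirements,
    )


def grade_part3(*parts: Part1Detail | Part2Detail | bool) -> bool:
    """Pass iff every supplied part passes."""
    if not parts:
        raise ValueError("part 3 needs at least one constituent grade")
    return all(p if isinstance(p, bool) else p.passed for p in parts)


def part1_requirements_for(n_comparisons: int) -> Part1Requirements:
    """Requirement constants for a given comparison count.

    For the protocol's 99 comparisons this returns the standard
    requirements; otherwise the required counts are scaled
    proportionally (rounded up), preserving the pass fractions.  Useful
    for exploratory cohorts of nonstandard size; the protocol itself is
    defined only at n=99.
    """
    std = Part1Requirements()
    if n_comparisons == std.n_comparisons:
        return std
    scale = n_comparisons / std.n_comparisons
    return Part1Requirements(
        n_comparisons=n_comparisons,
        two_of=tuple(math.ceil(t * scale) for t in std.two_of),  # type: ignore[arg-type]
        all_of=tuple(math.ceil(a * scale) for a in std.all_of),  # type: ignore[arg-type]
    )


def part2_requirements_for(n_subjects: int) -> Part2Requirements:
    """Requirement constants for a given subject count (scaled when != 33)."""
    std = Part2Requirements()
    if n_subjects == std.n_subjects:
        return std
    scale = n_subjects / std.n_subjects
    return Part2Requirements(
        n_subjects=n_subjects,
        min_subjects_2of3=math.ceil(std.min_subjects_2of3 * scale),
        max_subjects_0of3=math.floor(std.max_subjects_0of3 * scale),
    )


@dataclass(frozen=True)
class ParameterGrade:
    """All grading output for one parameter."""

    parameter: str
    thresholds: BandThresholds
    part1: Part1Detail
    part2: Part2Detail
    agreement: AgreementSummary


@dataclass(frozen=True)
class DeviceGradeReport:
    """Full validation outcome for a dataset.

    ``bp_part3`` combines the SBP and DBP Part 1/2 grades; ``hr_part3``
    stands alone.  ``overall`` is the conjunction of both.
    """

    n_subjects: int
    selection_mode: SelectionMode
    parameters: "OrderedDict[str, ParameterGrade]"
    bp_part3: bool
    hr_part3: bool

    @property
    def overall(self) -> bool:
        return self.bp_part3 and self.hr_part3


def grade_device(
    records: Sequence[SequenceRecord],
    *,
    selection_mode: SelectionMode = "independent",
    bp_thresholds: BandThresholds = BP_BANDS,
    hr_thresholds: BandThresholds = HR_BANDS,
    part1_requirements: Part1Requirements | None = None,
    part2_requirements: Part2Requirements | None = None,
    expected_subjects: int = 33,
    loa_multiplier: float = 1.96,
) -> DeviceGradeReport:
    """Run the full validation on a dataset of nine-reading records.

    Deterministic: identical input yields an identical report.  The
    protocol prescribes 33 subjects; other sizes are accepted with a
    warning and proportionally scaled requirements (see
    :func:`part1_requirements_for`).
    """
    n = len(records)
    if n == 0:
        raise ValueError("empty dataset")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != n:
        raise ValueError("duplicate subject_id in dataset")
    if n != expected_subjects:
        warnings.warn(
            f"dataset has {n} subjects; the protocol prescribes "
            f"{expected_subjects} — requirements scaled proportionally",
            stacklevel=2,
        )
    req1 = part1_requirements or part1_requirements_for(3 * n)
    req2 = part2_requirements or part2_requirements_for(n)

    grades: "OrderedDict[str, ParameterGrade]" = OrderedDict()
    for parameter, thresholds in (
        ("sbp", bp_thresholds),
        ("dbp", bp_thresholds),
        ("hr", hr_thresholds),
    ):
        diffs = all_differences(records, parameter, mode=selection_mode)
        counts = band_counts(diffs, thresholds)
        part1 = grade_part1(counts, req1)
        profiles = subject_band_profiles(diffs, thresholds.first)
        part2 = grade_part2(profiles, req2)
        summary = difference_summary(diffs, loa_multiplier=loa_multiplier)
        grades[parameter] = ParameterGrade(
            parameter=parameter,
            thresholds=thresholds,
            part1=part1,
            part2=part2,
            agreement=summary,
        )

    bp_part3 = grade_part3(
        grades["sbp"].part1, grades["sbp"].part2,
        grades["dbp"].part1, grades["dbp"].part2,
    )
    hr_part3 = grade_part3(grades["hr"].part1, grades["hr"].part2)
    return DeviceGradeReport(
        n_subjects=n,
        selection_mode=selection_mode,
        parameters=grades,
        bp_part3=bp_part3,
        hr_part3=hr_part3,
    )
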