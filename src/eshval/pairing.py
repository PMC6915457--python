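"""Flanking-pair construction and favorable-comparison selection.

Each graded test reading (BP2, BP4, BP6) is flanked by two reference
readings (BP1/BP3, BP3/BP5, BP5/BP7).  The protocol compares the test
reading with both flanking references and keeps the comparison more
favorable to the device — the one with the smaller absolute difference.
Ties go to the preceding reference.

Two selection modes are provided:

``independent`` (default)
    Each parameter (SBP, DBP, HR) chooses its own flank per comparison.

``joint``
    SBP and DBP share one flank per comparison, chosen by the smaller
    summed absolute difference; HR still selects independently.

The distinction matters only when the two pressures disagree about
which flank is closer; the independent mode is the reading consistent
with per-measurement band counting over 99 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .model import (
    GRADED_TEST_SLOTS,
    PARAMETERS,
    SequenceRecord,
    Violation,
    validate_sequence,
)

__all__ = [
    "COMPARISON_SLOTS",
    "SelectionMode",
    "CandidatePair",
    "PairedDifference",
    "InvalidSequenceError",
    "candidate_pairs",
    "select_favorable",
    "all_differences",
]

#: comparison index -> (test slot, preceding reference, following reference)
COMPARISON_SLOTS: dict[int, tuple[str, str, str]] = {
    1: ("BP2", "BP1", "BP3"),
    2: ("BP4", "BP3", "BP5"),
    3: ("BP6", "BP5", "BP7"),
}

SelectionMode = Literal["independent", "joint"]


class InvalidSequenceError(ValueError):
    """Raised when a record offered for pairing fails schedule validation."""

    def __init__(self, subject_id: str, violations: Sequence[Violation]):
        self.subject_id = subject_id
        self.violations = tuple(violations)
        detail = "; ".join(str(v) for v in violations)
        super().__init__(f"subject {subject_id}: invalid sequence: {detail}")


@dataclass(frozen=True)
class CandidatePair:
    """One test reading with both flanking reference candidates, for one
    parameter."""

    subject_id: str
    comparison_index: int  # 1..3, for BP2/BP4/BP6
    parameter: str
    test_value: int
    preceding_value: int
    following_value: int

    @property
    def preceding_abs(self) -> int:
        return abs(self.test_value - self.preceding_value)

    @property
    def following_abs(self) -> int:
        return abs(self.test_value - self.following_value)


@dataclass(frozen=True)
class PairedDifference:
    """A resolved comparison: the test reading against its chosen flank.

    ``signed_difference`` is test minus reference; ``abs_difference`` is
    its magnitude and, by the favorable rule, never exceeds the rejected
    candidate's magnitude.
    """

    subject_id: str
    comparison_index: int
    parameter: str
    test_value: int
    reference_value: int
    flank: str  # "preceding" | "following"

    @property
    def signed_difference(self) -> int:
        return self.test_value - self.reference_value

    @property
    def abs_difference(self) -> int:
        return abs(self.signed_difference)


def candidate_pairs(record: SequenceRecord, parameter: str) -> list[CandidatePair]:
    """Build the three flanking candidates for one parameter.

    The record must pass :func:`eshval.model.validate_sequence`; BPA and
    BPB never appear in candidates.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    violations = validate_sequence(record)
    if violations:
        raise InvalidSequenceError(record.subject_id, violations)
    out = []
    for index, (test_slot, pre_slot, fol_slot) in COMPARISON_SLOTS.items():
        out.append(
            CandidatePair(
                subject_id=record.subject_id,
                comparison_index=index,
                parameter=parameter,
                test_value=record.reading(test_slot).value(parameter),
                preceding_value=record.reading(pre_slot).value(parameter),
                following_value=record.reading(fol_slot).value(parameter),
            )
        )
    return out


def _resolve(candidate: CandidatePair, flank: str) -> PairedDifference:
    reference = (
        candidate.preceding_value if flank == "preceding" else candidate.following_value
    )
    return PairedDifference(
        subject_id=candidate.subject_id,
        comparison_index=candidate.comparison_index,
        parameter=candidate.parameter,
        test_value=candidate.test_value,
        reference_value=reference,
        flank=flank,
    )


def select_favorable(candidate: CandidatePair) -> PairedDifference:
    """Pick the flank with the smaller absolute difference (tie: preceding)."""
    flank = "preceding" if candidate.preceding_abs <= candidate.following_abs else "following"
    return _resolve(candidate, flank)


def _joint_flank(sbp: CandidatePair, dbp: CandidatePair) -> str:
    pre = sbp.preceding_abs + dbp.preceding_abs
    fol = sbp.following_abs + dbp.following_abs
    return "preceding" if pre <= fol else "following"


def all_differences(
    records: Iterable[SequenceRecord],
    parameter: str,
    *,
    mode: SelectionMode = "independent",
) -> list[PairedDifference]:
    """Favorably selected differences for one parameter across a dataset.

    Returns three differences per record, ordered by record then
    comparison index.  In ``joint`` mode SBP and DBP share the flank
    minimizing their summed absolute difference; HR is always selected
    independently.
    """
    if mode not in ("independent", "joint"):
        raise ValueError(f"unknown selection mode {mode!r}")
    out: list[PairedDifference] = []
    for record in records:
        cands = candidate_pairs(record, parameter)
        if mode == "joint" and parameter in ("sbp", "dbp"):
            sbp_cands = (
                cands if parameter == "sbp" else candidate_pairs(record, "sbp")
            )
            dbp_cands = (
                cands if parameter == "dbp" else candidate_pairs(record, "dbp")
            )
            for cand, s, d in zip(cands, sbp_cands, dbp_cands):
                out.append(_resolve(cand, _joint_flank(s, d)))
        else:
            out.extend(select_favorable(c) for c in cands)
    return out
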