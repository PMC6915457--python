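"""Band counting and Part 1/2/3 grading."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eshval.grading import (
    BandCounts,
    SubjectBandProfile,
    band_counts,
    grade_device,
    grade_part1,
    grade_part2,
    grade_part3,
    part1_requirements_for,
    part2_requirements_for,
    subject_band_profiles,
)
from eshval.model import BP_BANDS, HR_BANDS, Part1Requirements, Part2Requirements

from conftest import diffs_with_abs, make_record


def part1_oracle(within, req: Part1Requirements) -> bool:
    """Independent truth-table reading of the Part 1 rule."""
    n_two = sum(w >= t for w, t in zip(within, req.two_of))
    return n_two >= 2 and all(w >= a for w, a in zip(within, req.all_of))


def part2_oracle(n_two, n_zero, req: Part2Requirements) -> bool:
    return n_two >= req.min_subjects_2of3 and n_zero <= req.max_subjects_0of3


def profiles_with_tallies(n_two: int, n_zero: int, n: int = 33):
    """Subject profiles realizing given 2-of-3 and 0-of-3 tallies."""
    tallies = [2] * n_two + [0] * n_zero + [1] * (n - n_two - n_zero)
    return [SubjectBandProfile(f"P{i:03d}", t) for i, t in enumerate(tallies)]


class TestBandCounts:
    def test_inclusive_cumulative_counting(self):
        counts = band_counts(diffs_with_abs([0, 5, 10, 15, 16]), BP_BANDS)
        assert counts.within == (2, 3, 4)
        assert counts.n == 5

    def test_empty_input_counts_to_zero(self):
        assert band_counts([], BP_BANDS) == BandCounts(0, (0, 0, 0))

    def test_mixed_parameters_rejected(self):
        diffs = diffs_with_abs([1, 2], "sbp") + diffs_with_abs([3], "dbp")
        with pytest.raises(ValueError, match="mixed"):
            band_counts(diffs, BP_BANDS)

    def test_random_draws_match_brute_force_recount(self):
        rng = np.random.default_rng(2024)
        draws = np.abs(np.round(rng.normal(0.0, 4.4, size=99))).astype(int)
        counts = band_counts(diffs_with_abs(draws), BP_BANDS)
        expected = []
        for cutoff in (5, 10, 15):
            total = 0
            for value in draws:
                if value <= cutoff:
                    total += 1
            expected.append(total)
        assert counts.within == tuple(expected)

    def test_non_cumulative_counts_rejected(self):
        with pytest.raises(ValueError, match="cumulative"):
            BandCounts(99, (50, 40, 60))


class TestGradePart1:
    @pytest.mark.parametrize(
        "within,expected",
        [
            ((81, 92, 96), True),    # two_of met everywhere, all_of met
            ((85, 95, 95), True),    # band 3 misses two_of 96 but bands 1-2 carry
            ((85, 94, 95), True),    # heart-rate style counts, same rule
            ((64, 99, 99), False),   # band 1 below the all_of floor 65
            ((73, 87, 92), False),   # band 3 below its all_of floor 93
            ((65, 87, 96), True),    # floors everywhere, two_of at bands 2-3
            ((73, 81, 96), True),    # two_of at bands 1 and 3 only
            ((73, 87, 93), True),    # two_of at bands 1-2, floor at band 3
            ((72, 86, 96), False),   # only one band reaches its two_of count
        ],
    )
    def test_pass_rule(self, within, expected):
        assert grade_part1(BandCounts(99, within)).passed is expected

    def test_wrong_comparison_count_rejected(self):
        with pytest.raises(ValueError, match="99"):
            grade_part1(BandCounts(98, (70, 85, 95)))

    def test_agrees_with_truth_table_on_reduced_grid(self):
        req = part1_requirements_for(12)
        for w1 in range(13):
            for w2 in range(w1, 13):
                for w3 in range(w2, 13):
                    counts = BandCounts(12, (w1, w2, w3))
                    assert grade_part1(counts, req).passed is part1_oracle(
                        (w1, w2, w3), req
                    )

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.tuples(st.integers(0, 99), st.integers(0, 99), st.integers(0, 99)))
    def test_monotone_in_every_band_count(self, raw):
        within = tuple(sorted(raw))
        detail = grade_part1(BandCounts(99, within))
        if not detail.passed:
            return
        for i in range(3):
            bumped = list(within)
            bumped[i] = min(99, bumped[i] + 1)
            bumped = tuple(sorted(bumped))
            assert grade_part1(BandCounts(99, bumped)).passed


class TestGradePart2:
    @pytest.mark.parametrize(
        "n_two,n_zero,expected",
        [(29, 2, True), (30, 0, True), (29, 1, True),
         (23, 0, False), (24, 4, False), (24, 3, True)],
    )
    def test_pass_rule(self, n_two, n_zero, expected):
        detail = grade_part2(profiles_with_tallies(n_two, n_zero))
        assert detail.passed is expected
        assert detail.n_with_two_of_three == n_two
        assert detail.n_with_zero_of_three == n_zero

    def test_wrong_subject_count_rejected(self):
        with pytest.raises(ValueError, match="33"):
            grade_part2(profiles_with_tallies(20, 0, n=30))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 33), st.integers(0, 33))
    def test_agrees_with_truth_table(self, n_two, n_zero):
        if n_two + n_zero > 33:
            return
        req = Part2Requirements()
        assert grade_part2(profiles_with_tallies(n_two, n_zero)).passed is part2_oracle(
            n_two, n_zero, req
        )

    def test_subject_profiles_from_differences(self):
        # subject P001: 3/3 within 5; P002: 1/3; P003: 0/3
        diffs = diffs_with_abs([0, 3, 5, 2, 6, 9, 7, 8, 20])
        profiles = subject_band_profiles(diffs, BP_BANDS.first)
        assert [p.n_within_first_band for p in profiles] == [3, 1, 0]

    def test_incomplete_subject_rejected(self):
        with pytest.raises(ValueError, match="expected 3"):
            subject_band_profiles(diffs_with_abs([1, 2, 3, 4]), 5)


class TestGradePart3:
    def test_all_pass_combinations(self):
        p1 = grade_part1(BandCounts(99, (81, 92, 96)))
        p2 = grade_part2(profiles_with_tallies(29, 2))
        assert grade_part3(p1, p2, p1, p2) is True
        failing = grade_part1(BandCounts(99, (60, 92, 96)))
        assert grade_part3(p1, p2, failing, p2) is False

    def test_needs_at_least_one_part(self):
        with pytest.raises(ValueError):
            grade_part3()


class TestRequirementScaling:
    def test_standard_sizes_return_published_constants(self):
        assert part1_requirements_for(99) == Part1Requirements()
        assert part2_requirements_for(33) == Part2Requirements()

    def test_scaled_requirements_preserve_fractions(self):
        req = part1_requirements_for(198)
        assert req.two_of == (146, 174, 192)
        req2 = part2_requirements_for(66)
        assert req2.min_subjects_2of3 == 48
        assert req2.max_subjects_0of3 == 6


class TestGradeDevice:
    def test_identity_device_passes_everything(self, identity_dataset):
        report = grade_device(identity_dataset)
        for grade in report.parameters.values():
            assert grade.part1.passed
            assert grade.part1.counts.within == (99, 99, 99)
            assert grade.part2.n_with_two_of_three == 33
            assert grade.part2.n_with_zero_of_three == 0
        assert report.bp_part3 and report.hr_part3 and report.overall

    def test_constant_sbp_bias_fails_part1(self):
        records = [
            make_record(f"S{i:03d}", test_offset=(20, 0, 0)) for i in range(1, 34)
        ]
        report = grade_device(records)
        sbp = report.parameters["sbp"]
        assert sbp.part1.counts.within == (0, 0, 0)
        assert not sbp.part1.passed
        assert not report.bp_part3
        assert report.parameters["dbp"].part1.passed
        assert report.hr_part3

    def test_heart_rate_uses_its_own_bands(self):
        # a 4 bpm offset is outside the first HR band (3) but inside the
        # second (5); the same offset on pressure sits inside the first
        # BP band (5).
        records = [
            make_record(f"S{i:03d}", test_offset=(4, 4, 4)) for i in range(1, 34)
        ]
        report = grade_device(records)
        assert report.parameters["sbp"].part1.counts.within == (99, 99, 99)
        hr = report.parameters["hr"]
        assert hr.part1.counts.within == (0, 99, 99)
        assert not hr.part1.passed
        assert not report.hr_part3

    def test_printed_count_structure_grades_as_expected(self):
        # realize cumulative counts (81, 92, 96) out of 99 and check the
        # full Part 1 + Part 2 pipeline on constructed differences
        larger = [10] * 11 + [15] * 4 + [16] * 3
        magnitudes = []
        for big in larger:                     # 18 subjects with one big miss
            magnitudes += [5, 5, big]
        magnitudes += [5] * 45                 # 15 subjects fully within 5
        diffs = diffs_with_abs(magnitudes)
        counts = band_counts(diffs, BP_BANDS)
        assert counts.within == (81, 92, 96)
        assert grade_part1(counts).passed
        profiles = subject_band_profiles(diffs, BP_BANDS.first)
        assert grade_part2(profiles).passed

    def test_nonstandard_size_warns_and_scales(self):
        records = [make_record(f"S{i:03d}") for i in range(1, 12)]
        with pytest.warns(UserWarning, match="33"):
            report = grade_device(records)
        assert report.parameters["sbp"].part1.counts.n == 33
        assert report.overall

    def test_duplicate_subjects_rejected(self):
        records = [make_record("S001"), make_record("S001")]
        with pytest.raises(ValueError, match="duplicate"):
            grade_device(records)

    def test_deterministic(self, identity_dataset):
        assert grade_device(identity_dataset) == grade_device(identity_dataset)
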