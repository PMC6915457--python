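"""Synthetic cohorts, device-error simulation, and pass probabilities."""

from __future__ import annotations

import math

import numpy as np
import pytest

from eshval.grading import grade_device
from eshval.model import validate_sequence
from eshval.pairing import all_differences
from eshval.simulate import (
    DEFAULT_TEST_DEVICE,
    ZERO_DEVICE,
    CohortModel,
    DeviceErrorModel,
    PhysiologyModel,
    TruncatedNormal,
    pass_probability,
    simulate_cohort,
    simulate_sequence,
    simulate_study,
)

QUIET = PhysiologyModel(sbp_jitter_sd=0.0, dbp_jitter_sd=0.0, hr_jitter_sd=0.0,
                        dbp_residual_sd=0.0)


def constant_truth(sbp=135.0, dbp=75.0, hr=70.0):
    return {"sbp": [sbp] * 9, "dbp": [dbp] * 9, "hr": [hr] * 9}


class TestTruncatedNormal:
    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            TruncatedNormal(0.0, 1.0, 5.0, 5.0)

    def test_draws_respect_bounds(self):
        tn = TruncatedNormal(70.0, 30.0, 45.0, 90.0)
        draws = tn.rvs(np.random.default_rng(0), size=500)
        assert draws.min() >= 45.0 and draws.max() <= 90.0


class TestSimulateCohort:
    def test_sex_split_is_exact_and_reproducible(self):
        cohort = simulate_cohort(seed=7)
        assert len(cohort) == 33
        assert sum(p.sex == "male" for p in cohort) == 18
        assert sum(p.sex == "female" for p in cohort) == 15
        assert cohort == simulate_cohort(seed=7)
        assert cohort != simulate_cohort(seed=8)

    def test_large_cohort_recovers_model_means(self):
        model = CohortModel(n_subjects=1000, n_male=500)
        cohort = simulate_cohort(model, seed=3)
        males = [p for p in cohort if p.sex == "male"]
        ages = np.array([p.age for p in males])
        dist = model.male.age
        se = dist.truncated_sd / math.sqrt(len(males))
        assert ages.mean() == pytest.approx(dist.truncated_mean, abs=3 * se)
        females = [p for p in cohort if p.sex == "female"]
        arms = np.array([p.arm_circumference_mm for p in females])
        dist = model.female.arm_circumference_mm
        se = dist.truncated_sd / math.sqrt(len(females))
        assert arms.mean() == pytest.approx(dist.truncated_mean, abs=3 * se)

    def test_bmi_is_derived_not_drawn(self):
        for p in simulate_cohort(seed=1):
            assert p.bmi == pytest.approx(p.weight_kg / (p.height_cm / 100) ** 2)


class TestSimulateSequence:
    def test_zero_error_zero_variability_gives_zero_differences(self):
        record = simulate_sequence(constant_truth(), ZERO_DEVICE, ZERO_DEVICE, 0)
        assert validate_sequence(record) == []
        for parameter in ("sbp", "dbp", "hr"):
            assert all(
                d.signed_difference == 0
                for d in all_differences([record], parameter)
            )

    def test_pure_bias_shows_up_as_constant_difference(self):
        biased = DeviceErrorModel(bias={"sbp": 20.0})
        record = simulate_sequence(constant_truth(), ZERO_DEVICE, biased, 0)
        diffs = all_differences([record], "sbp")
        assert [d.signed_difference for d in diffs] == [20, 20, 20]

    def test_fixed_seed_reproduces_record_exactly(self):
        noisy = DeviceErrorModel(noise_sd={"sbp": 5.0, "dbp": 4.0, "hr": 3.0})
        a = simulate_sequence(constant_truth(), noisy, noisy, 42)
        b = simulate_sequence(constant_truth(), noisy, noisy, 42)
        assert a == b

    def test_wrong_epoch_count_rejected(self):
        truth = constant_truth()
        truth["sbp"] = truth["sbp"][:8]
        with pytest.raises(ValueError, match="epochs"):
            simulate_sequence(truth, ZERO_DEVICE, ZERO_DEVICE, 0)


class TestSimulateStudy:
    def test_every_generated_record_is_valid(self):
        for seed in range(10):
            records, roster = simulate_study(seed=seed)
            assert len(records) == len(roster) == 33
            for record in records:
                assert validate_sequence(record) == []

    def test_adding_subjects_never_perturbs_earlier_ones(self):
        small = CohortModel(n_subjects=5, n_male=3)
        big = CohortModel(n_subjects=8, n_male=3)
        recs_small, roster_small = simulate_study(small, seed=9)
        recs_big, roster_big = simulate_study(big, seed=9)
        assert recs_big[:5] == recs_small
        assert roster_big[:5] == roster_small

    def test_bias_recovered_from_large_simulation(self):
        # with no within-subject variability and a noiseless reference,
        # favorable selection is a no-op and the mean signed difference
        # estimates the configured bias
        noise = 4.4
        test = DeviceErrorModel(bias={"sbp": 4.0}, noise_sd={"sbp": noise})
        cohort = CohortModel(n_subjects=334, n_male=167)
        records, _ = simulate_study(cohort, QUIET, ZERO_DEVICE, test, seed=21)
        diffs = all_differences(records, "sbp")
        mean = np.mean([d.signed_difference for d in diffs])
        se = noise / math.sqrt(len(diffs))
        # integer display rounding adds at most ~0.3 of extra spread
        assert mean == pytest.approx(4.0, abs=3 * se + 0.1)


class TestPassProbability:
    def test_zero_error_always_passes(self):
        result = pass_probability(
            physiology_model=QUIET, ref_model=ZERO_DEVICE, test_model=ZERO_DEVICE,
            n_replicates=10, seed=1,
        )
        assert all(e.probability == 1.0 for e in result.estimates.values())

    def test_gross_bias_never_passes(self):
        biased = DeviceErrorModel(bias={"sbp": 20.0},
                                  noise_sd=DEFAULT_TEST_DEVICE.noise_sd)
        result = pass_probability(test_model=biased, n_replicates=10, seed=2)
        assert result.estimates["sbp_part1"].probability == 0.0
        assert result.estimates["overall"].probability == 0.0
        ci = result.estimates["sbp_part1"]
        assert ci.ci_low == 0.0 and ci.ci_high < 0.4

    def test_noisier_devices_pass_less_often(self):
        probs = []
        for noise in (2.0, 8.0):
            test = DeviceErrorModel(bias={}, noise_sd={"sbp": noise})
            result = pass_probability(
                physiology_model=QUIET, ref_model=ZERO_DEVICE, test_model=test,
                n_replicates=40, seed=5,
            )
            probs.append(result.estimates["overall"].probability)
        assert probs[0] > probs[1]

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            pass_probability(n_replicates=0)
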