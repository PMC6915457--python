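"""Synthetic validation cohorts and device-error simulation.

Nothing in a published device validation deposits raw readings, so the
package ships a generator that emulates the statistical structure the
analysis assumes: a 33-subject cohort with the demographic profile of a
hemodialysis population (18 male / 15 female; elderly, wide
arm-circumference range), per-subject true blood pressure and heart
rate, reading-to-reading physiological variability over the 30-60 s
inter-measurement spacing, and two device-error models (reference and
test) with additive bias, optional proportional bias, Gaussian noise,
and integer display rounding.

The generative model per subject:

    truth[p][i] = baseline[p] + drift[p]*i + jitter[p]*z_i
    reading[slot][p] = round(truth[p][i] + bias[p]
                             + proportional[p]*truth[p][i]
                             + noise_sd[p]*e)

DBP baselines are drawn jointly with SBP (a fixed fraction of SBP plus
residual noise) so that systolic always exceeds diastolic by a
physiological margin.

Random streams are split per subject with :class:`numpy.random.SeedSequence`
spawning, so enlarging a cohort never perturbs earlier subjects' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .grading import DeviceGradeReport, grade_device
from .model import (
    DBP_RANGE,
    HR_RANGE,
    PARAMETERS,
    SBP_RANGE,
    SLOT_LABELS,
    ReadingTriplet,
    SequenceRecord,
    SubjectProfile,
    role_for,
)

__all__ = [
    "TruncatedNormal",
    "SexModel",
    "CohortModel",
    "PhysiologyModel",
    "DeviceErrorModel",
    "ZERO_DEVICE",
    "DEFAULT_REFERENCE_DEVICE",
    "DEFAULT_TEST_DEVICE",
    "SimulationError",
    "simulate_cohort",
    "simulate_sequence",
    "simulate_study",
    "PassEstimate",
    "PassProbabilityResult",
    "pass_probability",
]

_RANGES = {"sbp": SBP_RANGE, "dbp": DBP_RANGE, "hr": HR_RANGE}


class SimulationError(RuntimeError):
    """Raised when the generator cannot produce an in-range reading."""


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lower, upper].

    ``mean``/``sd`` parameterize the untruncated normal; the truncated
    distribution's own moments are exposed for recovery checks.
    """

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lower < self.upper:
            raise ValueError(f"infeasible truncation bounds [{self.lower}, {self.upper}]")

    def _ab(self) -> tuple[float, float]:
        return (self.lower - self.mean) / self.sd, (self.upper - self.mean) / self.sd

    def rvs(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            value = min(max(self.mean, self.lower), self.upper)
            return value if size is None else np.full(size, value)
        a, b = self._ab()
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=size, random_state=rng)

    @property
    def truncated_mean(self) -> float:
        if self.sd == 0:
            return min(max(self.mean, self.lower), self.upper)
        a, b = self._ab()
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    @property
    def truncated_sd(self) -> float:
        if self.sd == 0:
            return 0.0
        a, b = self._ab()
        return float(stats.truncnorm.std(a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class SexModel:
    """Demographic distributions for one sex (hemodialysis cohort defaults)."""

    age: TruncatedNormal
    weight_kg: TruncatedNormal
    height_cm: TruncatedNormal
    arm_circumference_mm: TruncatedNormal


# Defaults mirror an elderly dialysis cohort: 18 men, 15 women, mean age
# ~71 y, arm circumference 215-350 mm.  BMI is derived, never drawn.
_MALE = SexModel(
    age=TruncatedNormal(70.11, 11.11, 45.0, 90.0),
    weight_kg=TruncatedNormal(70.33, 13.66, 46.5, 100.0),
    height_cm=TruncatedNormal(166.61, 5.63, 155.0, 180.0),
    arm_circumference_mm=TruncatedNormal(262.50, 24.15, 220.0, 310.0),
)
_FEMALE = SexModel(
    age=TruncatedNormal(72.13, 11.69, 48.0, 91.0),
    weight_kg=TruncatedNormal(71.15, 18.31, 46.8, 101.0),
    height_cm=TruncatedNormal(157.13, 10.77, 141.0, 174.0),
    arm_circumference_mm=TruncatedNormal(273.0, 38.06, 215.0, 350.0),
)


@dataclass(frozen=True)
class CohortModel:
    """Cohort size, sex split, and per-sex demographic distributions.

    Sex allocation is deterministic (the first ``n_male`` subjects are
    male) so configured counts are matched exactly.  A small fraction of
    subjects is measured on the left arm, standing in for dialysis
    access (arteriovenous fistula) on the right.
    """

    n_subjects: int = 33
    n_male: int = 18
    male: SexModel = _MALE
    female: SexModel = _FEMALE
    left_arm_fraction: float = 3 / 33

    def __post_init__(self) -> None:
        if not 0 <= self.n_male <= self.n_subjects:
            raise ValueError("n_male must be between 0 and n_subjects")

    @property
    def n_female(self) -> int:
        return self.n_subjects - self.n_male


@dataclass(frozen=True)
class PhysiologyModel:
    """Subject-level true values and within-subject variability.

    ``sbp`` and ``hr`` baselines are drawn from truncated normals; the
    DBP baseline is ``dbp_fraction * SBP + N(0, dbp_residual_sd)``,
    clamped so SBP exceeds DBP by at least ``min_pulse_pressure``.
    Reading-to-reading jitter (mm Hg / bpm per 30-60 s epoch) and an
    optional linear drift per reading complete the nine-epoch truth.
    """

    sbp: TruncatedNormal = TruncatedNormal(135.0, 20.0, 90.0, 220.0)
    hr: TruncatedNormal = TruncatedNormal(72.0, 10.0, 40.0, 140.0)
    dbp_fraction: float = 0.556
    dbp_residual_sd: float = 4.6
    sbp_jitter_sd: float = 4.0
    dbp_jitter_sd: float = 3.0
    hr_jitter_sd: float = 3.0
    sbp_drift: float = 0.0
    dbp_drift: float = 0.0
    hr_drift: float = 0.0
    min_pulse_pressure: float = 15.0

    def __post_init__(self) -> None:
        for name in ("dbp_residual_sd", "sbp_jitter_sd", "dbp_jitter_sd", "hr_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def draw_truth(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Nine per-epoch true values for each parameter."""
        base_sbp = float(self.sbp.rvs(rng))
        base_dbp = self.dbp_fraction * base_sbp + float(rng.normal(0.0, self.dbp_residual_sd)) \
            if self.dbp_residual_sd > 0 else self.dbp_fraction * base_sbp
        base_dbp = min(max(base_dbp, DBP_RANGE[0] + 5.0),
                       base_sbp - self.min_pulse_pressure)
        base_hr = float(self.hr.rvs(rng))
        n = len(SLOT_LABELS)
        epochs = np.arange(n, dtype=float)
        jitter = {
            "sbp": self.sbp_jitter_sd, "dbp": self.dbp_jitter_sd, "hr": self.hr_jitter_sd,
        }
        drift = {"sbp": self.sbp_drift, "dbp": self.dbp_drift, "hr": self.hr_drift}
        base = {"sbp": base_sbp, "dbp": base_dbp, "hr": base_hr}
        truth: dict[str, np.ndarray] = {}
        for p in PARAMETERS:
            noise = rng.normal(0.0, jitter[p], size=n) if jitter[p] > 0 else np.zeros(n)
            truth[p] = base[p] + drift[p] * epochs + noise
        # keep the per-epoch pulse pressure positive even under jitter
        gap = truth["sbp"] - truth["dbp"]
        low = gap < 5.0
        truth["dbp"][low] = truth["sbp"][low] - 5.0
        return truth


def _param_map(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(PARAMETERS)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        return {p: float(value.get(p, 0.0)) for p in PARAMETERS}
    return {p: float(value) for p in PARAMETERS}


@dataclass(frozen=True)
class DeviceErrorModel:
    """Additive bias, proportional bias, noise, and display rounding.

    Reference and test devices carry independent instances.  ``observe``
    maps a true value to a displayed reading:
    ``round(truth + bias + proportional*truth + noise_sd*z)``.
    """

    bias: Mapping[str, float] = field(default_factory=dict)
    proportional: Mapping[str, float] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    round_to_int: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias", _param_map(self.bias))
        object.__setattr__(self, "proportional", _param_map(self.proportional))
        noise = _param_map(self.noise_sd)
        if any(v < 0 for v in noise.values()):
            raise ValueError("noise SDs must be non-negative")
        object.__setattr__(self, "noise_sd", noise)

    @classmethod
    def zero(cls) -> "DeviceErrorModel":
        return cls()

    def observe(self, parameter: str, true_value: float, rng: np.random.Generator) -> float:
        sd = self.noise_sd[parameter]
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        value = (
            true_value
            + self.bias[parameter]
            + self.proportional[parameter] * true_value
            + noise
        )
        return float(round(value)) if self.round_to_int else float(value)


#: A device that reports the truth exactly.
ZERO_DEVICE = DeviceErrorModel()

#: Default reference device: unbiased with small measurement noise.
DEFAULT_REFERENCE_DEVICE = DeviceErrorModel(
    noise_sd={"sbp": 2.0, "dbp": 2.0, "hr": 1.0},
)

#: Default test device: biases of the order reported for consumer
#: upper-arm monitors (~+4 mm Hg SBP, ~+2.4 DBP, ~+1.9 bpm HR).
DEFAULT_TEST_DEVICE = DeviceErrorModel(
    bias={"sbp": 4.0, "dbp": 2.4, "hr": 1.9},
    noise_sd={"sbp": 3.0, "dbp": 2.5, "hr": 2.0},
)


def _profile_for(index: int, sex: str, model: CohortModel,
                 rng: np.random.Generator) -> SubjectProfile:
    sex_model = model.male if sex == "male" else model.female
    height = float(sex_model.height_cm.rvs(rng))
    weight = float(sex_model.weight_kg.rvs(rng))
    age = float(sex_model.age.rvs(rng))
    arm_c = float(sex_model.arm_circumference_mm.rvs(rng))
    arm = "left" if rng.random() < model.left_arm_fraction else "right"
    return SubjectProfile(
        subject_id=f"S{index + 1:03d}",
        sex=sex,
        age=age,
        height_cm=height,
        weight_kg=weight,
        arm_circumference_mm=arm_c,
        arm=arm,
    )


def simulate_cohort(model: CohortModel = CohortModel(), seed=0) -> list[SubjectProfile]:
    """Draw a roster of subject profiles.

    Reproducible given ``seed``; sex counts match the configured split
    exactly.  Each subject has an independent spawned random stream, so
    growing ``n_subjects`` leaves earlier subjects unchanged.
    """
    children = _as_seedseq(seed).spawn(model.n_subjects)
    profiles = []
    for i, child in enumerate(children):
        sex = "male" if i < model.n_male else "female"
        profiles.append(_profile_for(i, sex, model, np.random.default_rng(child)))
    return profiles


def simulate_sequence(
    truth: Mapping[str, Sequence[float]],
    ref_model: DeviceErrorModel,
    test_model: DeviceErrorModel,
    seed_or_rng,
    *,
    subject_id: str = "S001",
    max_retries: int = 100,
) -> SequenceRecord:
    """Observe nine true epochs through the two device-error models.

    ``truth`` maps each parameter to nine per-epoch true values (epoch
    order equals slot order BPA..BP7).  Readings violating physiologic
    ranges or sbp > dbp are resampled up to ``max_retries`` times, then
    the simulation fails.
    """
    if isinstance(seed_or_rng, np.random.Generator):
        rng = seed_or_rng
    else:
        rng = np.random.default_rng(_as_seedseq(seed_or_rng))
    for p in PARAMETERS:
        if len(truth[p]) != len(SLOT_LABELS):
            raise ValueError(f"truth[{p!r}] must have {len(SLOT_LABELS)} epochs")
    slots: dict[str, ReadingTriplet] = {}
    for i, slot in enumerate(SLOT_LABELS):
        device = ref_model if role_for(slot) == "reference" else test_model
        for _ in range(max_retries):
            values = {p: device.observe(p, float(truth[p][i]), rng) for p in PARAMETERS}
            ok = all(
                _RANGES[p][0] <= values[p] <= _RANGES[p][1] for p in PARAMETERS
            ) and values["sbp"] > values["dbp"]
            if ok:
                slots[slot] = ReadingTriplet(
                    sbp=int(values["sbp"]), dbp=int(values["dbp"]), hr=int(values["hr"])
                )
                break
        else:
            raise SimulationError(
                f"subject {subject_id}, slot {slot}: no in-range reading "
                f"after {max_retries} attempts"
            )
    return SequenceRecord(subject_id=subject_id, slots=slots)


def simulate_study(
    cohort_model: CohortModel = CohortModel(),
    physiology_model: PhysiologyModel = PhysiologyModel(),
    ref_model: DeviceErrorModel = DEFAULT_REFERENCE_DEVICE,
    test_model: DeviceErrorModel = DEFAULT_TEST_DEVICE,
    seed=0,
) -> tuple[list[SequenceRecord], list[SubjectProfile]]:
    """One full synthetic validation study: records plus roster.

    Each subject's profile, true trajectory, and readings are drawn from
    that subject's own spawned stream; the dataset feeds
    :func:`eshval.grading.grade_device` directly.
    """
    children = _as_seedseq(seed).spawn(cohort_model.n_subjects)
    records: list[SequenceRecord] = []
    roster: list[SubjectProfile] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sex = "male" if i < cohort_model.n_male else "female"
        profile = _profile_for(i, sex, cohort_model, rng)
        truth = physiology_model.draw_truth(rng)
        record = simulate_sequence(
            truth, ref_model, test_model, rng, subject_id=profile.subject_id
        )
        roster.append(profile)
        records.append(record)
    return records, roster


@dataclass(frozen=True)
class PassEstimate:
    """Monte-Carlo pass probability with an exact binomial 95% CI."""

    n_pass: int
    n_replicates: int
    probability: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PassProbabilityResult:
    n_replicates: int
    estimates: Mapping[str, PassEstimate]


_PASS_KEYS = (
    "sbp_part1", "sbp_part2", "dbp_part1", "dbp_part2",
    "hr_part1", "hr_part2", "bp_part3", "hr_part3", "overall",
)


def _outcomes(report: DeviceGradeReport) -> dict[str, bool]:
    g = report.parameters
    return {
        "sbp_part1": g["sbp"].part1.passed,
        "sbp_part2": g["sbp"].part2.passed,
        "dbp_part1": g["dbp"].part1.passed,
        "dbp_part2": g["dbp"].part2.passed,
        "hr_part1": g["hr"].part1.passed,
        "hr_part2": g["hr"].part2.passed,
        "bp_part3": report.bp_part3,
        "hr_part3": report.hr_part3,
        "overall": report.overall,
    }


def pass_probability(
    cohort_model: CohortModel = CohortModel(),
    physiology_model: PhysiologyModel = PhysiologyModel(),
    ref_model: DeviceErrorModel = DEFAULT_REFERENCE_DEVICE,
    test_model: DeviceErrorModel = DEFAULT_TEST_DEVICE,
    *,
    n_replicates: int = 100,
    seed=0,
) -> PassProbabilityResult:
    """Monte-Carlo probability of passing each grading stage.

    Replicate streams are spawned from ``seed``, so two sweeps sharing a
    seed use common random numbers — the right setup for monotonicity
    comparisons across bias or noise levels.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = _as_seedseq(seed).spawn(n_replicates)
    tallies = {key: 0 for key in _PASS_KEYS}
    for child in children:
        records, _ = simulate_study(
            cohort_model, physiology_model, ref_model, test_model, seed=child
        )
        for key, passed in _outcomes(grade_device(records)).items():
            tallies[key] += passed
    estimates = {}
    for key, k in tallies.items():
        ci = stats.binomtest(k, n_replicates).proportion_ci(
            confidence_level=0.95, method="exact"
        )
        estimates[key] = PassEstimate(
            n_pass=k,
            n_replicates=n_replicates,
            probability=k / n_replicates,
            ci_low=float(ci.low),
            ci_high=float(ci.high),
        )
    return PassProbabilityResult(n_replicates=n_replicates, estimates=estimates)
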