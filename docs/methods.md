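# Methods

## Scope and data model

The package implements the analysis stage of an ESH-IP2 (2010 revision)
device validation: from per-subject nine-reading schedules to the Part
1/2/3 pass decisions and Bland–Altman agreement summaries. Device
physics (cuff inflation, oscillometric waveform processing) and the
protocol's observer-training and entry-BP distribution requirements are
out of scope; the latter are acquisition-stage constraints that leave no
trace in the per-reading data this package consumes.

Readings are stored as integers (mm Hg / bpm), matching what automated
monitors display. Nothing downstream rounds, so every difference is an
exact integer and band membership at a cutoff is never a floating-point
edge case. Band membership is inclusive: a difference of exactly
5 mm Hg counts as "within 5 mm Hg". Slot roles are a pure function of
the slot label; the entry (BPA) and device-detection (BPB) readings are
kept in the data model for completeness but the pairing stage never
consumes them.

Rest period, inter-reading interval (30–60 s) and measurement arm are
treated as acquisition annotations: they justify the within-subject
variability model below but do not gate grading.

## Favorable-comparison selection

Each graded test reading is compared against its preceding and
following reference readings; the comparison with the smaller absolute
difference is kept. Two interpretations are defensible when SBP and DBP
disagree about the closer flank:

- **independent** (default): each parameter picks its own flank per
  comparison. This is the reading consistent with counting 99
  per-measurement differences per parameter.
- **joint**: SBP and DBP share the flank minimizing their summed
  absolute difference; HR always selects independently. Provided as a
  sensitivity switch (`selection_mode`).

Ties go to the preceding reference in both modes — an arbitrary but
fixed rule; since tied candidates have equal absolute difference, the
choice can only affect the sign of the recorded difference, never a
band count.

Signed differences are test − reference throughout. Summaries report
the signed mean (the Bland–Altman bias), its SD, and the mean absolute
difference, clearly distinguished, since banded grading operates on
magnitudes while agreement analysis needs the signed convention.

## Grading

Part 1 passes when at least two of the three cumulative band counts
reach the higher requirement (73/87/96 of 99) and all three reach the
lower one (65/81/93). Part 2 passes when at least 24 of 33 subjects
have ≥ 2 of their 3 first-band differences and at most 3 subjects have
none. Part 3 is the conjunction of its constituents: SBP + DBP jointly
for blood pressure, HR separately. HR grading reuses the identical
machinery with cutoffs (3, 5, 8) bpm and the same Part 2 requirement
constants (≥ 24 / ≤ 3); the per-subject HR criterion is the first band,
3 bpm.

The graders require the protocol's exact sizes (99 comparisons, 33
subjects). `grade_device` accepts other cohort sizes for exploratory
use but warns and scales the requirement counts proportionally (ceil
for minima, floor for the 0-of-3 maximum), preserving the pass
fractions; the protocol proper is defined only at n = 33.

## Agreement

Limits of agreement are bias ± 1.96 SD (multiplier configurable), SD
with the n − 1 denominator; an n = 1 input reports SD 0 rather than
NaN. No regression-based proportional-bias correction is applied —
banded validation reports plot raw differences. Bland–Altman points are
(test + reference)/2 against the signed difference of the favorably
selected pairs (the pairs the grading actually used), exported as CSV
so any plotting layer can redraw the figure; a matplotlib rendering is
included.

## Synthetic studies

The generator's role is to exercise the analysis under controlled error
structure, not physiological fidelity.

**Cohort.** Per-sex truncated normals for age, weight, height and arm
circumference parameterized to an elderly hemodialysis population
(total: age 71.0 y (SD 11.2), arm circumference 267 mm (SD 31),
18 male / 15 female at n = 33); draws are truncated to the observed
min–max ranges and BMI is derived, never drawn. Sex allocation is
deterministic so configured counts are met exactly. About 3 of 33
subjects are assigned left-arm measurement, standing in for
arteriovenous-fistula access on the right arm.

**Physiology.** Subject baselines: SBP ~ N(135, 20²) truncated to
[90, 220] mm Hg, HR ~ N(72, 10²) truncated to [40, 140] bpm. These
level distributions are stated placeholders — validation reports
publish demographics, not BP level distributions — and live in one
place (`PhysiologyModel`) for overriding. DBP is drawn jointly as
0.556 × SBP + N(0, 4.6²), clamped to keep a ≥ 15 mm Hg pulse pressure,
which reproduces a DBP mean ≈ 75 and SD ≈ 12 while guaranteeing
SBP > DBP. Within-subject reading-to-reading jitter (per 30–60 s epoch)
defaults to SD 4 / 3 / 3 (SBP/DBP/HR) with optional linear drift,
defaults zero — constants chosen so that both pass and fail regimes are
reachable by realistic device-error settings.

**Devices.** Reference and test devices carry independent error models:
additive bias, proportional bias, Gaussian noise, and integer display
rounding (`round(truth + bias + prop·truth + σ·z)`). Defaults: an
unbiased reference with small noise (SD 2/2/1), and a test device with
biases +4.0 mm Hg SBP, +2.4 DBP, +1.9 bpm HR and noise SD 3/2.5/2 — the
order of bias reported for consumer upper-arm monitors. Out-of-range or
pressure-inverted readings are resampled (bounded retries, then a hard
error); under default settings resampling is essentially never
triggered.

**Random streams.** Seeds are expanded with `numpy.random.SeedSequence`
spawning, one child per subject (and one per Monte-Carlo replicate), so
enlarging a cohort or replicate count never perturbs earlier draws, and
two parameter sweeps sharing a seed use common random numbers — the
correct setup for monotonicity comparisons of pass probability across
bias or noise levels.

**What passing simulated studies does not show.** The generator's noise
is Gaussian, homoscedastic and exchangeable across subjects; real
oscillometric error in stiff-arteried or arrhythmic patients is none of
these. Green simulator-based checks certify the analysis pipeline, not
any physical device.

## Numerical and design choices

- Pass-probability confidence intervals are exact Clopper–Pearson
  (`scipy.stats.binomtest`), appropriate for the small replicate counts
  and probabilities near 0/1 these studies produce.
- Monte-Carlo problem sizes in the test suite: 100 seeds for the
  degenerate (error-free) and gross-bias regimes, ~10⁴ comparisons for
  bias recovery, 200 replicates per level on a four-point noise grid
  with common random numbers — sizes at which the checked effects are
  many standard errors wide.
- The zero-variability regime (no jitter, no device noise) is the
  identity oracle: every difference is exactly 0 and all parts must
  pass on every seed; with variability present, passing is
  probabilistic by design.
- The report's canonical form is JSON; markdown is a pure function of
  the JSON document, so re-rendering a saved report is byte-identical.
  Every constant that can affect a grade is echoed into the report's
  provenance block, with overrides from the defaults listed separately.

## Known limitations

- The 2002 IP, BHS and AAMI grading schemes are not implemented.
- Cohort screening covers age, sex balance and exclusion flags; it does
  not model the recruitment-range requirements for entry BP.
- No hypothesis tests on bias are performed (none are part of the
  protocol's decision rule).
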