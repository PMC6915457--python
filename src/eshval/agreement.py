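"""Bland-Altman agreement statistics for paired device differences.

The headline bias is the mean signed difference (test minus reference);
limits of agreement are bias +/- 1.96 x SD of the signed differences
(multiplier configurable).  The mean absolute difference is reported
alongside, since banded protocols grade magnitudes.  SD uses the n-1
denominator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pairing import PairedDifference

__all__ = [
    "AgreementSummary",
    "BlandAltmanPoint",
    "difference_summary",
    "summarize_values",
    "bland_altman",
    "export_points_csv",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class AgreementSummary:
    parameter: str
    n: int
    mean_signed_difference: float
    sd_signed_difference: float
    mean_absolute_difference: float
    loa_lower: float
    loa_upper: float
    loa_multiplier: float = 1.96


@dataclass(frozen=True)
class BlandAltmanPoint:
    """One comparison: mean of the paired values vs their signed difference."""

    subject_id: str
    comparison_index: int
    parameter: str
    mean: float
    difference: float


def summarize_values(
    values: Sequence[float], parameter: str, *, loa_multiplier: float = 1.96
) -> AgreementSummary:
    """Agreement summary from raw signed differences.

    With a single observation the SD (and hence the limits' half-width)
    is reported as 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty set of differences")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    half = loa_multiplier * sd
    return AgreementSummary(
        parameter=parameter,
        n=int(arr.size),
        mean_signed_difference=mean,
        sd_signed_difference=sd,
        mean_absolute_difference=float(np.abs(arr).mean()),
        loa_lower=mean - half,
        loa_upper=mean + half,
        loa_multiplier=loa_multiplier,
    )


def difference_summary(
    differences: Sequence[PairedDifference], *, loa_multiplier: float = 1.96
) -> AgreementSummary:
    """Summary (bias, SD, absolute mean, limits of agreement) for one parameter."""
    if not differences:
        raise ValueError("cannot summarize an empty set of differences")
    params = {d.parameter for d in differences}
    if len(params) > 1:
        raise ValueError(f"mixed parameters in one summary: {sorted(params)}")
    return summarize_values(
        [d.signed_difference for d in differences],
        parameter=params.pop(),
        loa_multiplier=loa_multiplier,
    )


def bland_altman(
    differences: Sequence[PairedDifference], *, loa_multiplier: float = 1.96
) -> tuple[list[BlandAltmanPoint], AgreementSummary]:
    """Per-comparison Bland-Altman points plus the agreement summary.

    Point *i* has abscissa (test + reference)/2 and ordinate the signed
    difference of comparison *i*.
    """
    summary = difference_summary(differences, loa_multiplier=loa_multiplier)
    points = [
        BlandAltmanPoint(
            subject_id=d.subject_id,
            comparison_index=d.comparison_index,
            parameter=d.parameter,
            mean=(d.test_value + d.reference_value) / 2.0,
            difference=float(d.signed_difference),
        )
        for d in differences
    ]
    return points, summary


def export_points_csv(points: Sequence[BlandAltmanPoint], path) -> None:
    """Write points as CSV (subject_id, comparison_index, parameter, mean,
    difference) so any plotting layer can redraw the figure."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "comparison_index", "parameter", "mean", "difference"])
        for p in points:
            writer.writerow([p.subject_id, p.comparison_index, p.parameter, p.mean, p.difference])


def plot_bland_altman(
    points: Sequence[BlandAltmanPoint],
    summary: AgreementSummary,
    ax=None,
):
    """Render the difference-vs-mean scatter with bias and LoA lines.

    Returns the matplotlib axes.  Imported lazily so headless pipelines
    never touch a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter([p.mean for p in points], [p.difference for p in points],
               s=18, alpha=0.7, edgecolor="none")
    ax.axhline(summary.mean_signed_difference, color="k", lw=1.2, label="bias")
    for y in (summary.loa_lower, summary.loa_upper):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("Mean of test and reference")
    ax.set_ylabel("Difference (test - reference)")
    ax.set_title(summary.parameter.upper())
    return ax
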