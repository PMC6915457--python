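"""Validation report: a schema-stable JSON document plus markdown rendering.

JSON is the single source of truth; the markdown tables (requirements
vs achieved per band, per-part grades, agreement summaries, cohort
screening, config provenance) are rendered purely from the JSON dict,
so re-rendering a saved report reproduces the markdown byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

from .config import RunConfig
from .grading import DeviceGradeReport, ParameterGrade
from .model import PARAMETER_LABELS, ScreeningReport

__all__ = ["SCHEMA", "report_dict", "render_markdown", "write_report", "load_report"]

SCHEMA = "eshval-report/1"

_GRADE = {True: "Pass", False: "Fail"}


def _parameter_dict(grade: ParameterGrade) -> dict[str, Any]:
    p1, p2, a = grade.part1, grade.part2, grade.agreement
    return {
        "units": grade.thresholds.units,
        "cutoffs": list(grade.thresholds.cutoffs),
        "part1": {
            "n_comparisons": p1.counts.n,
            "achieved": list(p1.counts.within),
            "requirements": {
                "two_of": list(p1.requirements.two_of),
                "all_of": list(p1.requirements.all_of),
            },
            "n_two_of_met": p1.n_two_of_met,
            "bands_meeting_all_of": [b.meets_all_of for b in p1.bands],
            "grade": _GRADE[p1.passed],
        },
        "part2": {
            "n_subjects": p2.n_subjects,
            "n_with_two_of_three": p2.n_with_two_of_three,
            "n_with_zero_of_three": p2.n_with_zero_of_three,
            "requirements": {
                "min_subjects_2of3": p2.requirements.min_subjects_2of3,
                "max_subjects_0of3": p2.requirements.max_subjects_0of3,
            },
            "grade": _GRADE[p2.passed],
        },
        "agreement": {
            "n": a.n,
            "mean_signed_difference": a.mean_signed_difference,
            "sd_signed_difference": a.sd_signed_difference,
            "mean_absolute_difference": a.mean_absolute_difference,
            "loa_lower": a.loa_lower,
            "loa_upper": a.loa_upper,
            "loa_multiplier": a.loa_multiplier,
        },
    }


def _screening_dict(screening: ScreeningReport) -> dict[str, Any]:
    return {
        "n_included": screening.n_included,
        "n_male": screening.n_male,
        "n_female": screening.n_female,
        "included_ids": list(screening.included_ids),
        "excluded": {sid: list(reasons) for sid, reasons in screening.excluded.items()},
        "grade": _GRADE[screening.passed],
        "problems": list(screening.problems),
    }


def report_dict(
    report: DeviceGradeReport,
    screening: ScreeningReport | None = None,
    config: RunConfig | None = None,
) -> dict[str, Any]:
    """Assemble the canonical report document."""
    config = config or RunConfig()
    return {
        "schema": SCHEMA,
        "n_subjects": report.n_subjects,
        "selection_mode": report.selection_mode,
        "parameters": {
            name: _parameter_dict(grade) for name, grade in report.parameters.items()
        },
        "part3": {
            "blood_pressure": _GRADE[report.bp_part3],
            "heart_rate": _GRADE[report.hr_part3],
            "overall": _GRADE[report.overall],
        },
        "screening": _screening_dict(screening) if screening is not None else None,
        "config": {
            "values": config.to_dict(),
            "overridden_from_defaults": config.overrides(),
        },
    }


def _md_part1(name: str, p: Mapping[str, Any]) -> list[str]:
    cutoffs = p["cutoffs"]
    units = p["units"]
    one = p["part1"]
    header = " | ".join(f"<={c} {units}" for c in cutoffs)
    lines = [
        f"### Part 1 — {PARAMETER_LABELS.get(name, name)}",
        "",
        f"| | {header} | Grade |",
        "|---|" + "---|" * (len(cutoffs) + 1),
        "| Two of | " + " | ".join(str(v) for v in one["requirements"]["two_of"]) + " | |",
        "| All of | " + " | ".join(str(v) for v in one["requirements"]["all_of"]) + " | |",
        "| Achieved | "
        + " | ".join(str(v) for v in one["achieved"])
        + f" | {one['grade']} |",
        "",
    ]
    return lines


def _md_part2(name: str, p: Mapping[str, Any]) -> list[str]:
    two = p["part2"]
    first = p["cutoffs"][0]
    units = p["units"]
    return [
        f"### Part 2 — {PARAMETER_LABELS.get(name, name)}",
        "",
        f"| | 2/3 <={first} {units} | 0/3 <={first} {units} | Grade |",
        "|---|---|---|---|",
        f"| Required | >={two['requirements']['min_subjects_2of3']} "
        f"| <={two['requirements']['max_subjects_0of3']} | |",
        f"| Achieved | {two['n_with_two_of_three']} "
        f"| {two['n_with_zero_of_three']} | {two['grade']} |",
        "",
    ]


def render_markdown(doc: Mapping[str, Any]) -> str:
    """Render the report document as markdown (pure function of the dict)."""
    lines: list[str] = [
        "# Device validation report",
        "",
        f"Subjects: {doc['n_subjects']} — favorable-flank selection: "
        f"{doc['selection_mode']}",
        "",
    ]
    if doc.get("screening"):
        s = doc["screening"]
        lines += [
            "## Cohort screening",
            "",
            f"Included: {s['n_included']} ({s['n_male']} male / {s['n_female']} female)"
            f" — {s['grade']}",
            "",
        ]
        if s["excluded"]:
            for sid, reasons in s["excluded"].items():
                lines.append(f"- excluded {sid}: {', '.join(reasons)}")
            lines.append("")
        for problem in s["problems"]:
            lines.append(f"- problem: {problem}")
        if s["problems"]:
            lines.append("")
    order = [p for p in ("sbp", "dbp", "hr") if p in doc["parameters"]]
    order += [p for p in doc["parameters"] if p not in order]
    for name in order:
        p = doc["parameters"][name]
        lines += _md_part1(name, p)
        lines += _md_part2(name, p)
        a = p["agreement"]
        lines += [
            f"Mean difference (test − reference): "
            f"{a['mean_signed_difference']:.2f} (SD {a['sd_signed_difference']:.2f}) "
            f"{p['units']}; mean |difference| {a['mean_absolute_difference']:.2f}; "
            f"limits of agreement {a['loa_lower']:.2f} to {a['loa_upper']:.2f}.",
            "",
        ]
    part3 = doc["part3"]
    lines += [
        "## Part 3",
        "",
        f"- Blood pressure (SBP + DBP): {part3['blood_pressure']}",
        f"- Heart rate: {part3['heart_rate']}",
        f"- Overall: {part3['overall']}",
        "",
        "## Provenance",
        "",
        "```json",
        json.dumps(doc["config"], indent=2, sort_keys=True),
        "```",
        "",
    ]
    return "\n".join(lines)


def write_report(doc: Mapping[str, Any], json_path, md_path=None) -> None:
    """Write the JSON document (and optionally its markdown rendering)."""
    Path(json_path).write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if md_path is not None:
        Path(md_path).write_text(render_markdown(doc), encoding="utf-8")


def load_report(json_path) -> dict[str, Any]:
    doc = json.loads(Path(json_path).read_text(encoding="utf-8"))
    if doc.get("schema") != SCHEMA:
        raise ValueError(f"{json_path}: unexpected report schema {doc.get('schema')!r}")
    return doc
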