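"""Run configuration: every constant that can affect a grade, in one place.

Defaults are the protocol's published values.  A configuration is
echoed verbatim into the report's provenance block, and the block
additionally lists which fields differ from the defaults, so an
overridden constant is always visible even when the grades it produces
are unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .model import BandThresholds, Part1Requirements, Part2Requirements

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    bp_cutoffs: tuple[int, int, int] = (5, 10, 15)
    hr_cutoffs: tuple[int, int, int] = (3, 5, 8)
    part1_n_comparisons: int = 99
    part1_two_of: tuple[int, int, int] = (73, 87, 96)
    part1_all_of: tuple[int, int, int] = (65, 81, 93)
    part2_n_subjects: int = 33
    part2_min_subjects_2of3: int = 24
    part2_max_subjects_0of3: int = 3
    selection_mode: str = "independent"
    loa_multiplier: float = 1.96
    seed: int = 0
    log_level: str = "INFO"

    @property
    def bp_thresholds(self) -> BandThresholds:
        return BandThresholds(tuple(self.bp_cutoffs), "mm Hg")

    @property
    def hr_thresholds(self) -> BandThresholds:
        return BandThresholds(tuple(self.hr_cutoffs), "bpm")

    @property
    def part1_requirements(self) -> Part1Requirements:
        return Part1Requirements(
            n_comparisons=self.part1_n_comparisons,
            two_of=tuple(self.part1_two_of),
            all_of=tuple(self.part1_all_of),
        )

    @property
    def part2_requirements(self) -> Part2Requirements:
        return Part2Requirements(
            n_subjects=self.part2_n_subjects,
            min_subjects_2of3=self.part2_min_subjects_2of3,
            max_subjects_0of3=self.part2_max_subjects_0of3,
        )

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    def overrides(self) -> dict[str, Any]:
        """Fields whose values differ from the defaults."""
        default = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("bp_cutoffs", "hr_cutoffs", "part1_two_of", "part1_all_of"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
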