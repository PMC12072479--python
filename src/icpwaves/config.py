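"""Analysis configuration bundling every stage's tunables.

All thresholds that the clinical workflow applied by eye or by convention
are explicit here and can be loaded from a YAML file with sections
``preprocess:``, ``slow_waves:``, ``plateau:``, ``pulse:`` and
``decision:``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import ArtifactParams, FilterConfig
from .pulse_analysis import PulseParams
from .slow_waves import PlateauParams, SlowWaveParams

__all__ = ["AnalysisConfig"]


def _build(cls, d: dict | None):
    d = d or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a full recording analysis.

    strict_10h reproduces the nominal fixed 600-min night denominator for
    wave percentages instead of the actual nocturnal window length;
    criterion_b_basis chooses whether criterion B's ">10% of recording
    time" refers to the nocturnal window (default, matching how wave
    percentages are defined) or the total recording.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    slow_waves: SlowWaveParams = field(default_factory=SlowWaveParams)
    plateau: PlateauParams = field(default_factory=PlateauParams)
    pulse: PulseParams = field(default_factory=PulseParams)
    strict_10h: bool = False
    criterion_b_basis: str = "nocturnal"  # nocturnal | total

    def __post_init__(self) -> None:
        if self.criterion_b_basis not in ("nocturnal", "total"):
            raise ValueError("criterion_b_basis must be 'nocturnal' or 'total'")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        pre = d.get("preprocess", {})
        return cls(
            filter=_build(FilterConfig, {k: v for k, v in pre.items() if k == "window_length"}),
            artifacts=_build(ArtifactParams, {k: v for k, v in pre.items() if k != "window_length"}),
            slow_waves=_build(SlowWaveParams, d.get("slow_waves")),
            plateau=_build(PlateauParams, d.get("plateau")),
            pulse=_build(PulseParams, d.get("pulse")),
            **(d.get("decision") or {}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
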