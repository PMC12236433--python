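"""Run configuration: decision thresholds and windowing defaults.

Defaults follow the analysis conventions of the study design this package
models: a correlation screen at r > 0.5 with p < 0.01, a difference/total
ratio cut of 0.5, taxon fold-change flags at 3x (and its reciprocal),
transcript flags at |log2FC| > 2 with FDR q < 0.05, and pathway retention
requiring more than two significant member transcripts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Thresholds", "RunConfig"]

WINDOW_MODES = ("at_or_above_dcm", "custom")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds used by the screening and flagging stages."""

    r_min: float = 0.5            # minimum Pearson r vs the target ecotype
    diff_total_min: float = 0.5   # minimum difference/total ratio D
    p_corr_max: float = 0.01      # correlation p-value cut (0.05 variant optional)
    fc_flag: float = 3.0          # taxon fold-change flag, strict inequality
    log2fc_flag: float = 2.0      # transcript |log2FC| flag, strict inequality
    q_max: float = 0.05           # BH-adjusted p cut
    pathway_min_transcripts: int = 3  # "more than two" -> at least 3 members

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive, got {v}")
        if not 0 < self.q_max < 1:
            raise ValueError(f"q_max must lie in (0,1), got {self.q_max}")


@dataclass(frozen=True)
class RunConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    window_mode: str = "at_or_above_dcm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_mode not in WINDOW_MODES:
            raise ValueError(f"window_mode must be one of {WINDOW_MODES}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (by extension; YAML reads JSON too)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = data or {}
        thr = Thresholds(**data.pop("thresholds", {}))
        return cls(thresholds=thr, **data)

    def to_dict(self) -> dict:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "window_mode": self.window_mode,
            "seed": self.seed,
        }
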