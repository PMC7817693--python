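"""Pipeline configuration: one validated object shared by all stages.

Loaded from a YAML file (``--config``) or built from defaults; every run
writes the resolved configuration next to its outputs so results are
self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import CodeThresholds


@dataclass(frozen=True)
class PipelineConfig:
    thresholds: CodeThresholds = field(default_factory=CodeThresholds)
    max_mismatches: int = 3
    spacer_min: int = 0
    spacer_max: int = 0
    groove_window: int = 2
    seed: int = 0
    log_level: str = "warning"

    def __post_init__(self) -> None:
        if not (0 <= self.spacer_min <= self.spacer_max <= 13):
            raise ValueError("require 0 <= spacer_min <= spacer_max <= 13")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.groove_window < 0:
            raise ValueError("groove_window must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: expected a mapping")
        thr = raw.pop("thresholds", None)
        known = {f for f in cls.__dataclass_fields__ if f != "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        kwargs = dict(raw)
        if thr is not None:
            kwargs["thresholds"] = CodeThresholds(**thr)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
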