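"""Pipeline configuration: every constant the method leaves open.

Loaded from TOML; each field is validated against the constraints of
the module that consumes it.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .scoring import ScoreWeights

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    min_score: float = 1.0
    lam: float = 1.0
    max_mismatch: int = 1
    max_gap: int = 0
    min_similarity: float = 90.0
    min_perfect_adjacent: int = 3
    adjacency_gap_bp: int = 200
    alpha: float = 0.05
    log_scale_threshold: float = 50.0
    log_epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_mismatch < 0 or self.max_gap < 0:
            raise ValueError("filter thresholds must be nonnegative")
        if self.min_perfect_adjacent < 1 or self.adjacency_gap_bp < 0:
            raise ValueError("probe-set collapsing thresholds invalid")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    weights = ScoreWeights(**raw.pop("weights", {}))
    known = {f.name for f in fields(PipelineConfig)} - {"weights"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(weights=weights, **raw)
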