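"""Pipeline configuration: every mining threshold in one validated record.

All thresholds are user-changeable; the defaults are the method's reference
values: overlap FDR q <= 0.02, overlap expression q <= 0.02 with parent
q > 0.05, at least k = 10 supporting conditions, candidate targets at
|linear FC| >= 1.5 across ceil(0.3*k) supporting conditions, annotation
transfer at uncorrected p <= 1e-4, gene-set size window [10, 500].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    q_overlap: float = 0.02
    q_expr: float = 0.02
    q_parent: float = 0.05
    k: int = 10
    fc_threshold: float = 1.5
    frac: float = 0.3
    p0: float = 1e-4
    min_set: int = 10
    max_set: int = 500
    #: "matrix" restricts the universe to genes measured in the fold-change
    #: matrix (default); "sets" uses the union of set genes alone.
    universe_policy: str = "matrix"
    seed: int = 0
    #: strict '>' reading of the 0.3*k high-FC condition count
    strict_gt: bool = False
    #: count high-FC conditions over all conditions instead of supporting ones
    highfc_all_conditions: bool = False

    def validate(self) -> "PipelineConfig":
        for name in ("q_overlap", "q_expr", "q_parent"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if not (0.0 <= self.frac <= 1.0):
            raise ValueError("frac must lie in [0, 1]")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if not (1 <= self.min_set <= self.max_set):
            raise ValueError("require 1 <= min_set <= max_set")
        if self.universe_policy not in ("matrix", "sets"):
            raise ValueError("universe_policy must be 'matrix' or 'sets'")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw).validate()
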