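"""Study-level configuration: thresholds, paths, formulas, seed.

Centralizes the pipeline constants — artifact-screening parameters,
the 3-MET / 5-min bout rule, the 120-min recovery timeout and diary
match window, the 79.8-MET plausibility bound — in one YAML-backed
object, so a run is fully described by its config file plus a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .models import REACTIVITY_TERMS, RECOVERY_TERMS

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    input_dir: str = "dataset"
    output_dir: str = "out"

    # RR screening
    max_rel_change: float = 0.25
    rr_min: float = 300.0
    rr_max: float = 2000.0
    min_coverage: float = 0.8

    # event detection / recovery
    met_threshold: float = 3.0
    min_bout_minutes: int = 5
    recovery_timeout: int = 120
    diary_match_window: int = 120
    met_improbable: float = 79.8

    # model formulas (term lists on the model-ready tables)
    reactivity_terms: list[str] = field(default_factory=lambda: list(REACTIVITY_TERMS))
    recovery_terms: list[str] = field(default_factory=lambda: list(RECOVERY_TERMS))

    seed: int = 0

    def validate(self) -> None:
        for name in (
            "max_rel_change", "rr_min", "rr_max", "min_coverage",
            "met_threshold", "min_bout_minutes", "recovery_timeout",
            "diary_match_window", "met_improbable",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rr_min >= self.rr_max:
            raise ValueError("rr_min must be below rr_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of analysis-relevant settings (paths excluded)."""
        data = asdict(self)
        data.pop("input_dir")
        data.pop("output_dir")
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
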