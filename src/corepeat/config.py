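"""Pipeline configuration: thresholds, family lists, seed; YAML round-trip.

Defaults are the analysis thresholds the pipeline is built around: >2-fold
up-regulation at FDR 0.05, distance windows of 0/5/20 kb, 50 kb peak
clustering, 3 kb upstream regions, 80% conservation, 4-fold IP/input binding
enrichment, >5 kb full-length L1s, and family age cutoffs of 3 and 5 Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List

import yaml

from .simulate import INACTIVE_L1_FAMILIES, YOUNG_L1_FAMILIES


@dataclass
class PipelineConfig:
    seed: int = 0
    fold: float = 2.0
    fdr: float = 0.05
    use_adjusted_for_families: bool = True
    windows: List[int] = field(default_factory=lambda: [0, 5_000, 20_000])
    cluster_d: int = 50_000
    upstream_len: int = 3_000
    conservation_threshold: float = 0.8
    binding_ratio: float = 4.0
    full_length_min: int = 5_000
    age_cutoffs_myr: List[float] = field(default_factory=lambda: [3.0, 5.0])
    young_l1_families: List[str] = field(default_factory=lambda: list(YOUNG_L1_FAMILIES))
    inactive_l1_families: List[str] = field(
        default_factory=lambda: list(INACTIVE_L1_FAMILIES)
    )
    n_random_background: int = 100
    n_random_sets: int = 3
    paths: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positives = {
            "fold": self.fold,
            "fdr": self.fdr,
            "cluster_d": self.cluster_d,
            "upstream_len": self.upstream_len,
            "conservation_threshold": self.conservation_threshold,
            "binding_ratio": self.binding_ratio,
            "full_length_min": self.full_length_min,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"config: {name} must be positive, got {v}")
        if not self.windows or any(w < 0 for w in self.windows):
            raise ValueError("config: windows must be non-empty and non-negative")
        if any(c <= 0 for c in self.age_cutoffs_myr):
            raise ValueError("config: age cutoffs must be positive")
        if not self.young_l1_families:
            raise ValueError("config: young L1 family list must be non-empty")
        if not self.inactive_l1_families:
            raise ValueError("config: inactive L1 family list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
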