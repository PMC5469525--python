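"""Pipeline configuration: every tunable constant in one place.

Defaults reproduce the published protocol: M = 100 phase points per cycle,
50th-order 20 Hz FIR low-pass, channel-selection threshold r >= 0.75, two
cycles trimmed at each end of the walk, 4 AGGs of 3 cycles each, grey
distinguishing coefficient gamma = 1 and equal feature weights 0.2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    m: int = 100                        # samples per normalized cycle
    filter_order: int = 50              # FIR low-pass order
    filter_cutoff: float = 20.0         # Hz
    channel_threshold: float = 0.75     # channel-selection correlation threshold
    end_trim: int = 2                   # cycles dropped at each end of the walk
    n_aggs: int = 4                     # gait graphs per subject
    cycles_per_agg: int = 3
    gamma: float = 1.0                  # grey distinguishing coefficient
    weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    symmetry_band: tuple[float, float] = (0.3, 0.7)   # As search band, fraction of stride
    n_harmonics: int = 20
    center_channels: bool = True        # mean-center normalized cycles
    peak_threshold_sd: float = 0.2      # heel-strike amplitude threshold (in SDs)
    refractory_frac: float = 0.3        # minimum peak spacing, fraction of step period
    match_tolerance: int = 10           # samples, segmentation evaluation

    def __post_init__(self) -> None:
        self.weights = tuple(float(w) for w in self.weights)
        self.symmetry_band = tuple(self.symmetry_band)
        if not (0 < self.channel_threshold <= 1):
            raise ValueError("channel_threshold must be in (0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.m < 4 or self.n_aggs < 1 or self.cycles_per_agg < 1:
            raise ValueError("m, n_aggs and cycles_per_agg must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["weights"] = list(self.weights)
        d["symmetry_band"] = list(self.symmetry_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)
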