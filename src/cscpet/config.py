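"""Pipeline configuration shared by the CLI subcommands."""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Defaults are the study conditions: SUV 2.5 fixed threshold, 40%-of-SUVmax
    relative threshold, K=3 clusters (exact DP), 1.75 cm^3 response cutoff
    derived by rounding the pCR-group maximum up to the next 0.05 cm^3, and a
    36-month survival horizon.
    """

    fixed_threshold: float = 2.5  # SUV
    relative_fraction: float = 0.40
    k: int = 3
    clustering_method: str = "exact-dp"
    seed: int = 0
    cutoff: float = 1.75  # cm^3
    cutoff_round_up_step: float = 0.05  # cm^3
    survival_horizon: float = 36.0  # months

    def __post_init__(self) -> None:
        if self.fixed_threshold <= 0:
            raise ValueError("fixed threshold must be positive")
        if not 0 < self.relative_fraction < 1:
            raise ValueError("relative fraction must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be at least 2")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
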