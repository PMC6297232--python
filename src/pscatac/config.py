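"""Run configuration for the analysis pipeline.

Defaults encode the study's thresholds: a well/cell passes the technical
cutoff with more than ``min_reads`` total reads (default 10,000) and more
than ``min_map_rate`` mapped (default 0.90, strict inequalities); a
species-mixing well is a human singlet when the human:mouse read ratio
exceeds ``ratio_hi`` (default 10), a mouse singlet below ``ratio_lo``
(default 0.1), otherwise a doublet. Fragments with mapping quality below
``mapq_min`` (default 30) are discarded on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    mt_chrom: str = "chrM"
    min_reads: int = 10_000
    min_map_rate: float = 0.90
    ratio_hi: float = 10.0
    ratio_lo: float = 0.1
    mapq_min: int = 30
    n_svd: int = 50
    top_n_markers: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_map_rate <= 1):
            raise ValueError("min_map_rate must be in (0, 1]")
        if self.n_svd < 2:
            raise ValueError("n_svd must be >= 2 (dimension 1 is a depth diagnostic)")
        if self.ratio_hi <= 0 or self.ratio_lo <= 0:
            raise ValueError("ratio thresholds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from a YAML mapping; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    extra = set(data) - known
    if extra:
        raise ValueError(f"unknown configuration keys: {sorted(extra)}")
    return RunConfig(**data)
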