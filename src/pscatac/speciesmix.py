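"""Barnyard (human/mouse mixing) well classification.

Each well of a mixed-species plate is summarised by its human and mouse
read counts. Wells failing the technical cutoff (more than 10,000 total
reads and more than 90% mapped, both strict) are ``failed``; among the
rest, the human:mouse ratio R = h/m calls the well ``human`` when
R > 10, ``mouse`` when R < 0.1, and ``doublet`` otherwise. Boundary
values (R exactly 10 or 0.1, total exactly 10,000, mapped exactly 0.90)
resolve away from a singlet/pass call, matching the strict "larger
than / less than" rule. m = 0 with h > 0 gives R = +inf, a human call;
h = m = 0 cannot pass the read cutoff, so an undefined ratio never
reaches classification.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = ["classify_wells", "summarize_calls", "collision_rate"]

CALLS = ("human", "mouse", "doublet", "failed")


def classify_wells(
    wells: pd.DataFrame, config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Classify species-mixing wells.

    ``wells`` needs columns ``well_id, human_reads, mouse_reads,
    total_reads, mapped_fraction``. Returns the table with added
    ``ratio`` and ``call`` columns; well order is irrelevant to every
    call.
    """
    if config is None:
        config = RunConfig()
    required = {"well_id", "human_reads", "mouse_reads", "total_reads", "mapped_fraction"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (wells[["human_reads", "mouse_reads", "total_reads"]] < 0).any().any():
        raise ValueError("read counts must be non-negative")

    out = wells.copy()
    h = out["human_reads"].to_numpy(dtype=float)
    m = out["mouse_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, h / np.where(m > 0, m, 1.0), np.inf)
    ratio = np.where((m == 0) & (h == 0), np.nan, ratio)
    out["ratio"] = ratio

    passed = (out["total_reads"] > config.min_reads) & (
        out["mapped_fraction"] > config.min_map_rate
    )
    call = np.full(len(out), "doublet", dtype=object)
    call[ratio > config.ratio_hi] = "human"
    call[ratio < config.ratio_lo] = "mouse"
    call[~passed.to_numpy()] = "failed"
    out["call"] = call
    return out


def summarize_calls(calls: pd.DataFrame) -> pd.Series:
    """Counts per call category, plus successful-well and singlet totals."""
    counts = calls["call"].value_counts()
    summary = pd.Series({c: int(counts.get(c, 0)) for c in CALLS})
    summary["successful"] = int(summary["human"] + summary["mouse"] + summary["doublet"])
    summary["singlets"] = int(summary["human"] + summary["mouse"])
    return summary


def collision_rate(summary: pd.Series) -> float:
    """Doublet fraction among successful wells: doublets / (singlets + doublets)."""
    successful = summary["singlets"] + summary["doublet"]
    if successful == 0:
        return math.nan
    return float(summary["doublet"]) / float(successful)
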