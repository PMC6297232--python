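"""Per-cell quality control for plate-based scATAC-seq.

Metrics per cell: total reads *t* (fragment records before
deduplication), unique fragments *u* after coordinate deduplication,
duplication rate ``1 - u/t``, mitochondrial fraction, FRiP (fraction of
deduplicated non-mitochondrial fragments overlapping the peak set), and
the estimated library size L̂ obtained by inverting the Lander-Waterman
relation

    u = L (1 - exp(-t / L)),

the same model behind Picard's ``EstimateLibraryComplexity``. A cell
passes the technical cutoff with more than ``min_reads`` total reads and
more than ``min_map_rate`` of reads mapped (both strict).

Saturation analysis subsamples reads per cell without replacement and
re-deduplicates, tracing how many unique fragments a lower sequencing
depth would have captured.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .intervals import IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "dedup",
    "estimate_library_size",
    "fragments_in_peaks",
    "cell_qc",
    "filter_cells",
    "insert_size_hist",
    "TssProfile",
    "tss_enrichment",
    "saturation_curve",
]

_DEDUP_KEY = ["cell_id", "chrom", "start", "end"]


def dedup(fragments: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per distinct (cell_id, chrom, start, end).

    Identical coordinates in *different* cells are distinct fragments:
    each well is an independent library. Idempotent.
    """
    return fragments.drop_duplicates(subset=_DEDUP_KEY).reset_index(drop=True)


def estimate_library_size(t: int, u: int, rel_tol: float = 1e-9) -> float:
    """Invert u = L(1 - exp(-t/L)) for the latent library size L.

    Returns NaN when ``u == t`` (no duplicates observed; the root
    diverges). Bracketed bisection to relative tolerance ``rel_tol``.
    """
    if u <= 0:
        raise ValueError(f"unique count must be positive, got {u}")
    if u > t:
        raise ValueError(f"unique count {u} exceeds total reads {t}")
    if u == t:
        return math.nan

    def f(L: float) -> float:
        # L(1 - e^{-t/L}) - u, stable for large L via expm1
        return -L * math.expm1(-t / L) - u

    lo = float(u)
    hi = max(2.0 * u, float(t))
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - u==t already excluded
            return math.nan
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= rel_tol * hi:
            break
    return 0.5 * (lo + hi)


def fragments_in_peaks(fragments: pd.DataFrame, peaks: IntervalSet) -> np.ndarray:
    """Boolean array: does each fragment overlap (>=1 bp) any peak?

    Peaks must be sorted and non-overlapping (binary-search sweep).
    """
    peaks = peaks.sort()
    if peaks.has_overlaps():
        raise ValueError("peak set has overlaps; merge first")
    hit = np.zeros(len(fragments), dtype=bool)
    pdf = peaks.df
    for chrom, pchunk in pdf.groupby("chrom", sort=False):
        mask = (fragments["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = pchunk["start"].to_numpy()
        ends = pchunk["end"].to_numpy()
        fs = fragments.loc[mask, "start"].to_numpy()
        fe = fragments.loc[mask, "end"].to_numpy()
        lo = np.searchsorted(ends, fs, side="right")
        hi_ = np.searchsorted(starts, fe, side="left") - 1
        hit[mask] = hi_ >= lo
    return hit


def cell_qc(
    fragments: pd.DataFrame,
    peaks: IntervalSet,
    config: Optional[RunConfig] = None,
    mapped_counts: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-cell QC table from a raw (duplicate-containing) fragment table.

    ``mapped_counts`` optionally maps cell_id to mapping rate (aligned /
    total reads from the aligner); unaligned reads never reach the
    fragment table, so the rate cannot be derived here. FRiP is computed
    on deduplicated, non-mitochondrial fragments and is NaN when a cell
    has none.
    """
    if config is None:
        config = RunConfig()
    cells = sorted(fragments["cell_id"].unique())
    t = fragments.groupby("cell_id").size()
    ddf = dedup(fragments)
    u = ddf.groupby("cell_id").size()
    mt = ddf.groupby("cell_id")["is_mt"].mean() if "is_mt" in ddf.columns else None

    non_mt = ddf[~ddf["is_mt"]] if "is_mt" in ddf.columns else ddf
    in_peak = fragments_in_peaks(non_mt, peaks) if len(non_mt) else np.zeros(0, bool)
    denom = non_mt.groupby("cell_id").size()
    numer = pd.Series(in_peak, index=non_mt["cell_id"].values).groupby(level=0).sum()

    rows = []
    for cell in cells:
        ti = int(t.get(cell, 0))
        ui = int(u.get(cell, 0))
        dup = 1.0 - ui / ti if ti > 0 else math.nan
        mti = float(mt.get(cell, math.nan)) if mt is not None else math.nan
        di = int(denom.get(cell, 0))
        frip = float(numer.get(cell, 0)) / di if di > 0 else math.nan
        lhat = estimate_library_size(ti, ui) if 0 < ui <= ti else math.nan
        mapped = float(mapped_counts[cell]) if mapped_counts and cell in mapped_counts else math.nan
        rows.append((cell, ti, ui, dup, mti, frip, lhat, mapped))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "total_reads",
            "unique_fragments",
            "duplication_rate",
            "mt_fraction",
            "frip",
            "est_library_size",
            "mapped_fraction",
        ],
    )


def filter_cells(qc_table: pd.DataFrame, config: Optional[RunConfig] = None) -> pd.Series:
    """Technical cutoff: total reads > min_reads AND mapping rate > min_map_rate.

    Both inequalities strict. When mapping rates are unavailable (all
    NaN) that clause is skipped with a warning.
    """
    if config is None:
        config = RunConfig()
    passes = qc_table["total_reads"] > config.min_reads
    mapped = qc_table["mapped_fraction"]
    if mapped.notna().any():
        passes = passes & (mapped > config.min_map_rate)
    else:
        logger.warning("mapping rates unavailable; mapping-rate filter skipped")
    return pd.Series(passes.to_numpy(), index=qc_table["cell_id"].to_numpy(), name="pass")


def insert_size_hist(fragments: pd.DataFrame, max_size: int = 1000) -> np.ndarray:
    """Histogram of insert sizes (end - start).

    Returns an array of length ``max_size + 2``: index ``s`` holds the
    count of fragments with insert size ``s`` for ``1 <= s <= max_size``;
    the final slot pools everything larger. Index 0 is always 0.
    """
    hist = np.zeros(max_size + 2, dtype=np.int64)
    if len(fragments) == 0:
        return hist
    sizes = (fragments["end"] - fragments["start"]).to_numpy()
    clipped = np.where(sizes > max_size, max_size + 1, sizes)
    np.add.at(hist, clipped, 1)
    return hist


@dataclass
class TssProfile:
    """Mean per-base fragment coverage around TSS, strand-oriented."""

    window: int
    profile: np.ndarray  # length 2*window + 1, positions -window..window
    enrichment_score: float
    n_tss: int
    flagged: bool = False  # True when the flank normaliser was zero

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)


def tss_enrichment(
    fragments: pd.DataFrame,
    tss: IntervalSet,
    window: int = 2_000,
    flank: int = 100,
) -> TssProfile:
    """Aggregate fragment coverage in ±window around each TSS.

    Minus-strand TSS contributions are flipped so "downstream" always
    points right. The enrichment score is the centre value divided by the
    mean coverage of the two outermost ``flank``-bp edges; NaN (flagged)
    when the edges have zero coverage.
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty")
    width = 2 * window + 1
    total = np.zeros(width, dtype=float)
    tdf = tss.sort().df
    max_len = int((fragments["end"] - fragments["start"]).max()) if len(fragments) else 0

    frag_by_chrom = {
        c: g.sort_values("start") for c, g in fragments.groupby("chrom", observed=True)
    }
    for row in tdf.itertuples(index=False):
        p = (row.start + row.end) // 2
        win_lo, win_hi = p - window, p + window + 1
        chunk = frag_by_chrom.get(row.chrom)
        cov = np.zeros(width, dtype=float)
        if chunk is not None and len(chunk):
            starts = chunk["start"].to_numpy()
            ends = chunk["end"].to_numpy()
            i0 = np.searchsorted(starts, win_lo - max_len, side="left")
            i1 = np.searchsorted(starts, win_hi, side="left")
            s = starts[i0:i1]
            e = ends[i0:i1]
            keep = e > win_lo
            s, e = s[keep], e[keep]
            if len(s):
                a = np.clip(s - win_lo, 0, width)
                b = np.clip(e - win_lo, 0, width)
                diff = np.zeros(width + 1)
                np.add.at(diff, a, 1.0)
                np.add.at(diff, b, -1.0)
                cov = np.cumsum(diff)[:-1]
        if row.strand == "-":
            cov = cov[::-1]
        total += cov

    profile = total / len(tdf)
    edges = np.concatenate([profile[:flank], profile[-flank:]])
    baseline = float(edges.mean())
    centre = float(profile[window])
    if baseline > 0:
        return TssProfile(window, profile, centre / baseline, len(tdf))
    return TssProfile(window, profile, math.nan, len(tdf), flagged=True)


def saturation_curve(
    fragments: pd.DataFrame,
    fractions: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Unique fragments recovered at subsampled sequencing depth.

    For each fraction f, round(f * t) reads are drawn per cell without
    replacement (a prefix of one seeded per-cell permutation, so the
    subsamples are nested and the curve is monotone by construction) and
    deduplication re-run. Fraction 1.0 reproduces the full-depth unique
    count exactly. Returns a frame with columns fraction, n_reads,
    n_unique, duplication_rate.
    """
    fractions = list(fractions)
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    perms = {
        c: rng.permutation(g.index.to_numpy())
        for c, g in fragments.groupby("cell_id")
    }
    rows = []
    for f in fractions:
        kept_idx = []
        for cell in sorted(perms):
            idx = perms[cell]
            n_keep = len(idx) if f >= 1.0 else int(round(f * len(idx)))
            if n_keep > 0:
                kept_idx.append(idx[:n_keep])
        sub = fragments.loc[np.concatenate(kept_idx)] if kept_idx else fragments.iloc[:0]
        n_reads = len(sub)
        n_unique = len(dedup(sub))
        dup_rate = 1.0 - n_unique / n_reads if n_reads else math.nan
        rows.append((f, n_reads, n_unique, dup_rate))
    return pd.DataFrame(rows, columns=["fraction", "n_reads", "n_unique", "duplication_rate"])
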