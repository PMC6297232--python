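"""Peak-by-cell accessibility matrices.

The reference peak set is the union (bedtools-merge semantics) of the
input peak sets. Counting follows the any-overlap rule: a deduplicated
fragment increments every peak it overlaps by at least 1 bp, so a
fragment spanning two adjacent peaks counts once in each. Binarization
labels a peak "open" (1) for a cell when at least one fragment overlaps
it, "closed" (0) otherwise.

Counting is a sorted sweep over non-overlapping peaks using binary
search, O((n + m) log m) for n fragments and m peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .intervals import IntervalSet, merge_intervals

__all__ = [
    "AccessibilityMatrix",
    "merge_peak_sets",
    "count_matrix",
    "binarize",
    "annotate_peaks",
]


@dataclass
class AccessibilityMatrix:
    """Sparse peak (rows) by cell (columns) fragment counts.

    ``binarized`` is the open/closed indicator view: 1 iff count >= 1.
    """

    counts: sp.csr_matrix
    peak_ids: List[str]
    cell_ids: List[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.peak_ids = list(self.peak_ids)
        self.cell_ids = list(self.cell_ids)
        if self.counts.shape != (len(self.peak_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.peak_ids)} peaks x {len(self.cell_ids)} cells"
            )
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise ValueError("duplicate peak identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def binarized(self) -> sp.csr_matrix:
        b = self.counts.copy()
        b.data = (b.data >= 1).astype(np.int64)
        b.eliminate_zeros()
        return b

    def total_mass(self) -> int:
        return int(self.counts.sum())


def merge_peak_sets(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Union of peak sets into a sorted, non-overlapping reference set."""
    return merge_intervals(sets, name_prefix="peak")


def _peak_ids(peaks: IntervalSet) -> List[str]:
    df = peaks.df
    ids = []
    for row in df.itertuples(index=False):
        ids.append(
            row.name
            if row.name is not None and not pd.isna(row.name)
            else f"{row.chrom}:{row.start}-{row.end}"
        )
    if len(set(ids)) != len(ids):
        raise ValueError("peak identifiers not unique")
    return ids


def count_matrix(fragments: pd.DataFrame, peaks: IntervalSet) -> AccessibilityMatrix:
    """Count deduplicated fragments overlapping each reference peak per cell.

    Requires a sorted, non-overlapping peak set (run
    :func:`merge_peak_sets` first); raises otherwise. Fragments are taken
    as given — deduplicate upstream.
    """
    peaks = peaks.sort()
    if peaks.has_overlaps():
        raise ValueError("peak set has overlaps; merge_peak_sets must be applied first")
    peak_names = _peak_ids(peaks)
    cell_ids = sorted(fragments["cell_id"].unique()) if len(fragments) else []
    cell_index = {c: i for i, c in enumerate(cell_ids)}

    pdf = peaks.df
    rows_all: List[np.ndarray] = []
    cols_all: List[np.ndarray] = []
    peak_offset = 0
    # peaks are grouped per chromosome in sorted order
    for chrom, pchunk in pdf.groupby("chrom", sort=False):
        starts = pchunk["start"].to_numpy()
        ends = pchunk["end"].to_numpy()
        fchunk = fragments[fragments["chrom"] == chrom]
        if len(fchunk) and len(pchunk):
            fs = fchunk["start"].to_numpy()
            fe = fchunk["end"].to_numpy()
            # first peak whose end > fragment start; last peak whose start < fragment end
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left") - 1
            reps = np.clip(hi - lo + 1, 0, None)
            total = int(reps.sum())
            if total:
                within = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
                rows_all.append(peak_offset + np.repeat(lo, reps) + within)
                cells = fchunk["cell_id"].map(cell_index).to_numpy()
                cols_all.append(np.repeat(cells, reps))
        peak_offset += len(pchunk)

    shape = (len(peak_names), len(cell_ids))
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        counts = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=shape
        ).tocsr()
    else:
        counts = sp.csr_matrix(shape, dtype=np.int64)
    return AccessibilityMatrix(counts=counts, peak_ids=peak_names, cell_ids=cell_ids)


def binarize(matrix: AccessibilityMatrix) -> AccessibilityMatrix:
    """Open/closed indicator matrix; idempotent."""
    return AccessibilityMatrix(
        counts=matrix.binarized, peak_ids=matrix.peak_ids, cell_ids=matrix.cell_ids
    )


def annotate_peaks(
    peaks: IntervalSet,
    tss: IntervalSet,
    promoter_bp: int = 1_000,
    genic_bp: int = 10_000,
) -> pd.DataFrame:
    """Assign each peak its nearest gene by TSS midpoint distance.

    Signed distance is peak midpoint minus TSS position (negative when the
    peak lies upstream of the TSS coordinate). Categories: ``promoter``
    within ``promoter_bp``; ``genic`` within ``genic_bp`` (a gene-body
    proxy — no gene models are consulted); ``distal`` beyond. Equidistant
    TSS ties resolve to the lexicographically smaller gene name. Peaks on
    chromosomes without any TSS get an undefined distance, category
    ``distal``, and a ``flagged`` mark.
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty")
    tdf = tss.sort().df.copy()
    # TSS position: the annotated site itself (end-1 for minus-strand records)
    tdf["pos"] = np.where(tdf["strand"] == "-", tdf["end"] - 1, tdf["start"]).astype(float)
    tdf["gene"] = [
        n if n is not None and not pd.isna(n) else f"tss_{i}"
        for i, n in enumerate(tdf["name"])
    ]

    records = []
    peak_names = _peak_ids(peaks.sort())
    pdf = peaks.sort().df
    by_chrom = {c: g.sort_values("pos") for c, g in tdf.groupby("chrom")}
    for pid, row in zip(peak_names, pdf.itertuples(index=False)):
        mid = (row.start + row.end) / 2.0
        chunk = by_chrom.get(row.chrom)
        if chunk is None:
            records.append((pid, None, np.nan, "distal", True))
            continue
        pos = chunk["pos"].to_numpy()
        genes = chunk["gene"].to_numpy()
        j = np.searchsorted(pos, mid)
        cand = [k for k in (j - 1, j) if 0 <= k < len(pos)]
        dists = np.abs(mid - pos[cand])
        best = np.min(dists)
        best_genes = sorted(genes[k] for k, d in zip(cand, dists) if d == best)
        # equal-distance TSS may also share a coordinate further along
        gene = best_genes[0]
        signed = mid - pos[cand[int(np.argmin(dists))]]
        # re-derive sign for the chosen gene if the tie spans both sides
        for k, d in zip(cand, dists):
            if d == best and genes[k] == gene:
                signed = mid - pos[k]
                break
        adist = abs(signed)
        if adist <= promoter_bp:
            cat = "promoter"
        elif adist <= genic_bp:
            cat = "genic"
        else:
            cat = "distal"
        records.append((pid, gene, float(signed), cat, False))
    return pd.DataFrame(
        records, columns=["peak_id", "gene", "distance", "category", "flagged"]
    )
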