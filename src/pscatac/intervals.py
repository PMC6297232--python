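"""Genomic interval primitives with BED (0-based, half-open) semantics.

Peaks and TSS annotations are carried as :class:`IntervalSet`, a thin
numpy/pandas-backed container of sorted intervals. Merging and overlap
queries follow ``bedtools`` conventions: book-ended intervals merge, and
any overlap of >= 1 bp counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "IntervalSet", "merge_intervals"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Coordinates are 0-based; ``end`` is exclusive. ``strand`` is optional
    and only meaningful for oriented features such as TSS records.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Internally a DataFrame with columns ``chrom, start, end, name, strand``.
    ``sorted`` means ordered by ``(chrom, start, end)``; most downstream
    operations (overlap counting, merging) require sorted input.
    """

    COLUMNS = ("chrom", "start", "end", "name", "strand")

    def __init__(self, df: pd.DataFrame, *, is_sorted: bool = False):
        df = df.copy()
        for col in ("name", "strand"):
            if col not in df.columns:
                df[col] = None
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["end"] <= df["start"]).any():
            bad = df.index[df["end"] <= df["start"]][0]
            raise ValueError(f"empty or inverted interval at row {bad}")
        if (df["chrom"].astype(str) == "").any():
            raise ValueError("empty chromosome name")
        self._df = df
        self.is_sorted = bool(is_sorted)

    # ---------------------------------------------------------------- build
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df).sort()

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        name: Optional[Sequence[str]] = None,
        strand: Optional[Sequence[str]] = None,
    ) -> "IntervalSet":
        df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
        if name is not None:
            df["name"] = name
        if strand is not None:
            df["strand"] = strand
        return cls(df).sort()

    # ------------------------------------------------------------ interface
    def sort(self) -> "IntervalSet":
        if self.is_sorted:
            return self
        df = self._df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(df, is_sorted=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom,
                int(row.start),
                int(row.end),
                None if pd.isna(row.name) else row.name,
                None if row.strand in (None, "", ".") or pd.isna(row.strand) else row.strand,
            )

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self._df.iloc[i]
        return GenomicInterval(
            row["chrom"],
            int(row["start"]),
            int(row["end"]),
            row["name"] if row["name"] not in (None,) and not pd.isna(row["name"]) else None,
            row["strand"] if row["strand"] not in (None, ".") and not pd.isna(row["strand"]) else None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self._df[["chrom", "start", "end"]]
        b = other._df[["chrom", "start", "end"]]
        if len(a) != len(b):
            return False
        return bool((a.values == b.values).all())

    @property
    def names(self) -> pd.Series:
        return self._df["name"]

    def total_bp(self) -> int:
        return int((self._df["end"] - self._df["start"]).sum())

    def has_overlaps(self) -> bool:
        """True if any two intervals on the same chromosome overlap (>=1 bp)."""
        df = self.sort()._df
        same_chrom = df["chrom"].values[1:] == df["chrom"].values[:-1]
        overlap = df["start"].values[1:] < df["end"].values[:-1]
        return bool(np.any(same_chrom & overlap))


def merge_intervals(sets: Sequence[IntervalSet], *, name_prefix: str = "peak") -> IntervalSet:
    """Union of interval sets with bedtools-merge semantics.

    Overlapping or book-ended (distance 0) intervals collapse into maximal
    intervals; the result is sorted and non-overlapping. Merged intervals
    get fresh sequential names ``{name_prefix}_{i}``.
    """
    if len(sets) == 0:
        raise ValueError("merge requires at least one interval set")
    df = pd.concat([s.df for s in sets], ignore_index=True)
    if df.empty:
        raise ValueError("cannot merge empty interval sets")
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")

    out_chrom: list = []
    out_start: list = []
    out_end: list = []
    cur_chrom = None
    cur_start = cur_end = -1
    for chrom, start, end in zip(df["chrom"].values, df["start"].values, df["end"].values):
        if chrom != cur_chrom or start > cur_end:  # book-ended start == cur_end merges
            if cur_chrom is not None:
                out_chrom.append(cur_chrom)
                out_start.append(cur_start)
                out_end.append(cur_end)
            cur_chrom, cur_start, cur_end = chrom, start, end
        else:
            cur_end = max(cur_end, end)
    out_chrom.append(cur_chrom)
    out_start.append(cur_start)
    out_end.append(cur_end)

    names = [f"{name_prefix}_{i}" for i in range(len(out_chrom))]
    res = IntervalSet(
        pd.DataFrame(
            {"chrom": out_chrom, "start": out_start, "end": out_end, "name": names}
        ),
        is_sorted=True,
    )
    return res
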