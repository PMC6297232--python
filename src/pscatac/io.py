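"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* BED3/4/6 for peaks and TSS (0-based half-open; ``track``/``browser``/``#``
  header lines are skipped).
* Fragments TSV: ``chrom  start  end  cell_id  [mapq]``, optionally
  gzip-compressed (detected by file magic, not extension). One row per
  aligned fragment (a read pair collapsed to its Tn5 insertion interval);
  duplicates are expected and removed downstream.
* Peak-by-cell count matrices as MatrixMarket coordinate files with
  plain-text peak-name and cell-name sidecars.
* FASTA for peak sequences (via Biopython) and plain-text PFM motif files
  (4 rows A/C/G/T of counts or probabilities; HOMER/JASPAR-style ``>``
  headers).

The in-memory fragment container is a pandas DataFrame with columns
``chrom, start, end, cell_id[, mapq], is_mt`` — the "fragment table" that
every downstream stage consumes.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import IntervalSet

__all__ = [
    "BedParseError",
    "FragmentFormatError",
    "read_bed",
    "write_bed",
    "read_fragments",
    "write_fragments",
    "read_matrix",
    "write_matrix",
    "read_fasta",
    "write_fasta",
    "read_pfm",
]

PathLike = Union[str, Path]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell_id"]


class BedParseError(ValueError):
    pass


class FragmentFormatError(ValueError):
    pass


def _open_text(path: PathLike):
    """Open possibly-gzipped text, sniffing the gzip magic bytes."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# --------------------------------------------------------------------- BED
def read_bed(path: PathLike) -> IntervalSet:
    """Read a BED3/4/6 file into a sorted :class:`IntervalSet`.

    Raises :class:`BedParseError` naming the offending line on malformed
    coordinates (non-integer, negative, or ``end <= start``).
    """
    chroms: List[str] = []
    starts: List[int] = []
    ends: List[int] = []
    names: List[Optional[str]] = []
    strands: List[Optional[str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0:
                raise BedParseError(f"{path}: line {lineno}: negative start {start}")
            if end <= start:
                raise BedParseError(
                    f"{path}: line {lineno}: empty interval ({start}, {end})"
                )
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 and fields[3] != "." else None)
            strands.append(fields[5] if len(fields) > 5 and fields[5] in "+-" else None)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "name": names, "strand": strands}
    )
    return IntervalSet(df).sort()


def write_bed(intervals: IntervalSet, path: PathLike) -> None:
    """Write an interval set as BED (6 columns when strand is present)."""
    df = intervals.df
    has_name = df["name"].notna().any()
    has_strand = df["strand"].notna().any()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end)]
            if has_name or has_strand:
                fields.append(row.name if pd.notna(row.name) else ".")
            if has_strand:
                fields.append("0")
                fields.append(row.strand if pd.notna(row.strand) else ".")
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------- fragments
def read_fragments(
    path: PathLike,
    mapq_min: int = 30,
    mt_chrom: str = "chrM",
) -> pd.DataFrame:
    """Read a 4/5-column fragments TSV into a sorted fragment table.

    Records with ``mapq < mapq_min`` are dropped when the optional fifth
    column is present (mirroring the upstream ``samtools -q 30`` filter);
    ``is_mt`` is set from ``mt_chrom``. The result is sorted by
    ``(cell_id, chrom, start)`` so reading is insensitive to input order.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        if not first:
            return _empty_fragment_table()
        ncol = len(first.rstrip("\n").split("\t"))
        if ncol not in (4, 5):
            raise FragmentFormatError(
                f"{path}: expected 4 or 5 tab-separated columns, found {ncol} "
                "(chrom, start, end, cell_id[, mapq])"
            )
    names = FRAGMENT_COLUMNS + (["mapq"] if ncol == 5 else [])
    with _open_text(path) as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            header=None,
            names=names,
            dtype={"chrom": str, "cell_id": str},
        )
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FragmentFormatError(f"{path}: non-integer coordinates") from exc
    if (df["start"] < 0).any():
        bad = int(df.index[df["start"] < 0][0]) + 1
        raise FragmentFormatError(f"{path}: line {bad}: negative start coordinate")
    if (df["end"] <= df["start"]).any():
        bad = int(df.index[df["end"] <= df["start"]][0]) + 1
        raise FragmentFormatError(f"{path}: line {bad}: insert size must be positive")
    if df["cell_id"].isna().any() or (df["cell_id"].astype(str) == "").any():
        raise FragmentFormatError(f"{path}: missing cell_id values")
    if "mapq" in df.columns:
        df = df[df["mapq"] >= mapq_min].copy()
    df["is_mt"] = df["chrom"] == mt_chrom
    df = df.sort_values(["cell_id", "chrom", "start", "end"], kind="mergesort")
    return df.reset_index(drop=True)


def write_fragments(fragments: pd.DataFrame, path: PathLike) -> None:
    """Write a fragment table as (optionally gzipped, by suffix) TSV."""
    cols = FRAGMENT_COLUMNS + (["mapq"] if "mapq" in fragments.columns else [])
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fragments[cols].to_csv(fh, sep="\t", header=False, index=False)


def _empty_fragment_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "cell_id": pd.Series(dtype=str),
            "is_mt": pd.Series(dtype=bool),
        }
    )


# ------------------------------------------------------------------ matrix
def write_matrix(matrix, prefix: PathLike) -> None:
    """Write an accessibility matrix as ``<prefix>.mtx`` plus name sidecars.

    Produces a MatrixMarket coordinate file (1-based indices, integer
    field) with ``<prefix>.peaks.txt`` and ``<prefix>.cells.txt`` holding
    the row and column identifiers, one per line.
    """
    prefix = str(prefix)
    counts = sp.coo_matrix(matrix.counts)
    if counts.shape != (len(matrix.peak_ids), len(matrix.cell_ids)):
        raise ValueError("matrix dimensions do not match identifier lists")
    scipy.io.mmwrite(prefix + ".mtx", counts, field="integer")
    Path(prefix + ".peaks.txt").write_text("\n".join(map(str, matrix.peak_ids)) + "\n")
    Path(prefix + ".cells.txt").write_text("\n".join(map(str, matrix.cell_ids)) + "\n")


def read_matrix(prefix: PathLike):
    """Read a matrix written by :func:`write_matrix`; exact round trip."""
    from .matrix import AccessibilityMatrix

    prefix = str(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx")).astype(np.int64)
    peaks = Path(prefix + ".peaks.txt").read_text().splitlines()
    cells = Path(prefix + ".cells.txt").read_text().splitlines()
    return AccessibilityMatrix(counts=counts, peak_ids=peaks, cell_ids=cells)


# ------------------------------------------------------------------- FASTA
def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` mapping (upper-cased)."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------- PFM
def read_pfm(path: PathLike) -> Dict[str, np.ndarray]:
    """Read plain-text PFM motifs: ``>name`` then 4 rows (A, C, G, T).

    Rows may be counts or probabilities; each motif is returned as a
    ``(4, width)`` float array in A/C/G/T order, un-normalised.
    """
    motifs: Dict[str, np.ndarray] = {}
    name = None
    rows: List[List[float]] = []

    def _flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {name!r}: expected 4 rows (A/C/G/T), got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"motif {name!r}: ragged PFM rows")
        motifs[name] = np.asarray(rows, dtype=float)

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                rows = []
            else:
                # tolerate a leading A:/C:/G:/T: tag
                parts = line.replace(":", " ").split()
                if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
                    parts = parts[1:]
                rows.append([float(x) for x in parts])
    _flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs
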