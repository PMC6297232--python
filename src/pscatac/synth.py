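"""Synthetic plate-based scATAC-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every pipeline stage is testable without sequencing
data:

* **Genome**: a few synthetic chromosomes carrying non-overlapping peaks.
  Each cluster owns a disjoint block of cluster-specific peaks (open only
  in that cluster); the remainder is constitutively open. Every tenth
  peak's midpoint doubles as a TSS, so fragments genuinely pile up around
  transcription start sites. One motif per cluster is planted (as an
  exact consensus instance) into that cluster's specific peaks.
* **Cells**: each cell has a latent library of exactly L distinct
  fragments — peak fragments target the cell's open peaks (with a small
  leak rate into closed peaks), the rest is uniform background — and the
  sequencer draws t reads *with replacement* from that library. The
  observed unique count u therefore follows the Lander-Waterman relation
  E[u] = L(1 - exp(-t/L)), and at the study's depth regime of t ~ 20 L
  the duplication rate is ~95%. A fraction ``mt_rate`` of the library is
  mitochondrial (median ~2% of reads in the emulated study).
* **Insert sizes**: log-normal mixture with nucleosome-free, mono- and
  di-nucleosome components centred near 75/200/400 bp (weights
  0.55/0.30/0.15), reproducing the nucleosomal banding of good ATAC
  libraries.
* **Species-mixing plates**: wells are human or mouse singlets, rare
  doublets drawing ~50/50 from both species, plus near-empty negative
  controls with only 100-1000 reads.

All randomness flows from one integer seed; per-cell substreams are
derived by counter, so adding cells never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .markers import MotifModel

__all__ = [
    "SyntheticGenome",
    "CellDesign",
    "make_genome",
    "make_motif",
    "default_designs",
    "simulate_cells",
    "simulate_species_plate",
    "emit_peak_sequences",
    "make_reference_profiles",
]

MT_SIZE = 16_299  # mouse mitochondrial genome length, bp


@dataclass
class SyntheticGenome:
    """Synthetic chromosomes, peaks, TSS and planted-motif plan."""

    chrom_sizes: Dict[str, int]
    peaks: IntervalSet
    tss: IntervalSet
    truth: np.ndarray  # (n_peaks, n_clusters) binary open/closed per cluster
    peak_strength: np.ndarray  # per-peak accessibility weight (heavy-tailed)
    motifs: Dict[str, MotifModel]
    motif_plan: Dict[str, List[str]]  # motif name -> peak names with a planted instance
    motif_cluster: Dict[str, int]  # motif name -> cluster it marks
    cluster_specific: Dict[int, List[str]]
    mt_chrom: str = "chrM"

    @property
    def n_clusters(self) -> int:
        return self.truth.shape[1]

    @property
    def peak_names(self) -> List[str]:
        return list(self.peaks.names)

    def open_peaks(self, cluster: int) -> np.ndarray:
        return np.where(self.truth[:, cluster] == 1)[0]


@dataclass
class CellDesign:
    """Latent design of one simulated cell.

    ``library_size`` L is the number of distinct fragments in the cell's
    library; ``depth`` t the number of reads drawn from it with
    replacement. ``frip`` is the fraction of nuclear library fragments
    placed inside peaks open for the cell's cluster; ``mt_rate`` the
    mitochondrial fraction of the library.
    """

    cell_id: str
    cluster: int
    library_size: int
    depth: int
    mt_rate: float = 0.02
    frip: float = 0.6
    insert_weights: Tuple[float, float, float] = (0.55, 0.30, 0.15)
    species: Optional[str] = None
    is_negative: bool = False

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not (0 <= self.mt_rate < 1):
            raise ValueError("mt_rate must be in [0, 1)")
        if abs(sum(self.insert_weights) - 1.0) > 1e-9:
            raise ValueError("insert mixture weights must sum to 1")


# ----------------------------------------------------------------- genome
def make_motif(name: str, rng: np.random.Generator, width: int = 12) -> MotifModel:
    """A random informative PWM: one dominant base per column (p=0.88)."""
    consensus = rng.integers(0, 4, size=width)
    pfm = np.full((4, width), 0.04)
    pfm[consensus, np.arange(width)] = 0.88
    return MotifModel(name=name, pfm=pfm)


def make_genome(
    n_chroms: int = 2,
    n_peaks: int = 1_200,
    n_clusters: int = 4,
    n_specific: int = 100,
    n_motifs: Optional[int] = None,
    peak_width: int = 500,
    seed: int = 0,
    chrom_size: Optional[int] = None,
    motif_width: int = 12,
    tss_every: int = 10,
) -> SyntheticGenome:
    """Build a synthetic genome with cluster-structured peak accessibility.

    Peaks are non-overlapping, ``peak_width`` bp wide, separated by
    random 1-3 kb gaps. Each of the ``n_clusters`` clusters receives a
    disjoint block of ``n_specific`` cluster-specific peaks; the rest are
    shared (open in every cluster). Motif i is planted into the specific
    peaks of cluster i. Deterministic for a fixed seed. If an explicit
    ``chrom_size`` cannot hold the requested peaks, a capacity error is
    raised.
    """
    if n_clusters < 1 or n_peaks < n_clusters:
        raise ValueError("need n_peaks >= n_clusters >= 1")
    if n_specific * n_clusters > n_peaks:
        raise ValueError("cluster-specific blocks exceed the number of peaks")
    if n_motifs is None:
        n_motifs = n_clusters
    rng = np.random.default_rng([seed, 0])

    per_chrom = [n_peaks // n_chroms + (1 if i < n_peaks % n_chroms else 0) for i in range(n_chroms)]
    chroms, starts, ends, names = [], [], [], []
    chrom_sizes: Dict[str, int] = {}
    idx = 0
    for ci, count in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(1_000, 3_000))
        for _ in range(count):
            starts.append(pos)
            ends.append(pos + peak_width)
            chroms.append(chrom)
            names.append(f"peak_{idx:05d}")
            idx += 1
            pos += peak_width + int(rng.integers(1_000, 3_000))
        size = pos + 10_000
        if chrom_size is not None:
            if size > chrom_size:
                raise ValueError(
                    f"cannot place {count} peaks of {peak_width} bp on a "
                    f"{chrom_size} bp chromosome without overlap"
                )
            size = chrom_size
        chrom_sizes[chrom] = size
    peaks = IntervalSet.from_arrays(chroms, starts, ends, name=names)

    # cluster plan: disjoint specific blocks drawn at random, remainder shared
    order = rng.permutation(n_peaks)
    truth = np.ones((n_peaks, n_clusters), dtype=np.int8)
    cluster_specific: Dict[int, List[str]] = {}
    name_arr = np.asarray(names)
    for c in range(n_clusters):
        block = order[c * n_specific : (c + 1) * n_specific]
        truth[block, :] = 0
        truth[block, c] = 1
        cluster_specific[c] = sorted(name_arr[block])

    # TSS at every tss_every-th peak midpoint, random strand
    t_chroms, t_starts, t_ends, t_names, t_strands = [], [], [], [], []
    for gi, pi in enumerate(range(0, n_peaks, tss_every)):
        mid = (starts[pi] + ends[pi]) // 2
        t_chroms.append(chroms[pi])
        t_starts.append(mid)
        t_ends.append(mid + 1)
        t_names.append(f"gene_{gi:04d}")
        t_strands.append("+" if rng.random() < 0.5 else "-")
    tss = IntervalSet.from_arrays(t_chroms, t_starts, t_ends, name=t_names, strand=t_strands)

    peak_strength: np.ndarray  # per-peak accessibility weight (heavy-tailed)
    # heavy-tailed per-peak accessibility: a few strong peaks carry much
    # of the signal, many weak peaks are seen only at depth (as in real ATAC)
    peak_strength = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)

    motifs: Dict[str, MotifModel] = {}
    motif_plan: Dict[str, List[str]] = {}
    motif_cluster: Dict[str, int] = {}
    for mi in range(n_motifs):
        name = f"TF{mi + 1}"
        motifs[name] = make_motif(name, rng, width=motif_width)
        c = mi % n_clusters
        motif_plan[name] = list(cluster_specific[c])
        motif_cluster[name] = c

    chrom_sizes["chrM"] = MT_SIZE
    return SyntheticGenome(
        chrom_sizes=chrom_sizes,
        peaks=peaks,
        tss=tss,
        truth=truth,
        peak_strength=peak_strength,
        motifs=motifs,
        motif_plan=motif_plan,
        motif_cluster=motif_cluster,
        cluster_specific=cluster_specific,
    )


# ------------------------------------------------------------------ cells
def default_designs(
    genome: SyntheticGenome,
    cells_per_cluster: int = 75,
    library_size_range: Tuple[int, int] = (600, 6_000),
    depth_ratio_range: Tuple[float, float] = (3.0, 20.0),
    mt_rate: float = 0.02,
    frip: float = 0.6,
    seed: int = 0,
) -> List[CellDesign]:
    """Standard cell panel: equal clusters, depth varying 10x independently.

    Per-cell library size L is log-uniform over ``library_size_range``
    (a 10x span by default) and sequencing depth t is L times a
    log-uniform ratio in ``depth_ratio_range`` (moderate sequencing up
    to the ~95%-duplication saturation regime). Both are drawn
    independently of the cluster label, so depth is a pure nuisance axis
    for the embedding.
    """
    rng = np.random.default_rng([seed, 1])

    def _loguniform(lo: float, hi: float) -> float:
        return math.exp(rng.uniform(math.log(lo), math.log(hi)))

    designs = []
    i = 0
    for c in range(genome.n_clusters):
        for _ in range(cells_per_cluster):
            L = int(round(_loguniform(*library_size_range)))
            ratio = _loguniform(*depth_ratio_range)
            designs.append(
                CellDesign(
                    cell_id=f"cell_{i:04d}",
                    cluster=c,
                    library_size=L,
                    depth=int(round(ratio * L)),
                    mt_rate=mt_rate,
                    frip=frip,
                )
            )
            i += 1
    return designs


_LOGNORM = {  # (median bp, sigma of log) per nucleosomal component
    0: (75.0, 0.35),
    1: (200.0, 0.18),
    2: (400.0, 0.12),
}


def _insert_sizes(rng: np.random.Generator, n: int, weights: Tuple[float, float, float]) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(weights))
    sizes = np.empty(n)
    for k, (median, sigma) in _LOGNORM.items():
        mask = comp == k
        if mask.any():
            sizes[mask] = np.exp(rng.normal(math.log(median), sigma, size=mask.sum()))
    return np.clip(sizes.round().astype(np.int64), 20, 1_000)


def _build_library(
    genome: SyntheticGenome, design: CellDesign, rng: np.random.Generator, eps: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exactly L distinct (chrom_code, start, end) latent fragments."""
    pdf = genome.peaks.df
    chrom_names = list(genome.chrom_sizes)
    chrom_code = {c: i for i, c in enumerate(chrom_names)}
    peak_chrom = pdf["chrom"].map(chrom_code).to_numpy()
    peak_start = pdf["start"].to_numpy()
    peak_end = pdf["end"].to_numpy()
    sizes = np.asarray([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    nuclear = np.asarray([c != genome.mt_chrom for c in chrom_names])
    nuc_weights = np.where(nuclear, sizes, 0.0)
    nuc_weights = nuc_weights / nuc_weights.sum()
    mt_code = chrom_code[genome.mt_chrom]

    open_idx = genome.open_peaks(design.cluster) if not design.is_negative else np.array([], int)
    closed_idx = np.setdiff1d(np.arange(len(pdf)), open_idx)
    if not design.is_negative and len(open_idx) == 0:
        raise ValueError(f"cluster {design.cluster} has no open peaks")

    L = design.library_size
    n_mt = int(round(design.mt_rate * L))
    n_nuc = L - n_mt
    n_peak = 0 if design.is_negative else int(round(design.frip * n_nuc))

    chroms = np.empty(0, np.int64)
    starts = np.empty(0, np.int64)
    ends = np.empty(0, np.int64)
    need = L
    for _ in range(20):
        draw = need
        s = _insert_sizes(rng, draw, design.insert_weights)
        c = np.empty(draw, np.int64)
        a = np.empty(draw, np.int64)
        # split the batch proportionally across peak / background / MT sources
        n_mt_b = int(round(draw * n_mt / L))
        n_peak_b = int(round(draw * n_peak / L)) if L else 0
        n_bg_b = draw - n_mt_b - n_peak_b
        j = 0
        if n_peak_b:
            w_open = genome.peak_strength[open_idx]
            tgt = rng.choice(open_idx, size=n_peak_b, p=w_open / w_open.sum())
            if len(closed_idx):
                leak = rng.random(n_peak_b) < eps
                if leak.any():
                    w_cl = genome.peak_strength[closed_idx]
                    tgt[leak] = rng.choice(
                        closed_idx, size=int(leak.sum()), p=w_cl / w_cl.sum()
                    )
            mid = rng.uniform(peak_start[tgt], peak_end[tgt])
            c[j : j + n_peak_b] = peak_chrom[tgt]
            a[j : j + n_peak_b] = np.maximum(0, (mid - s[j : j + n_peak_b] / 2).astype(np.int64))
            j += n_peak_b
        if n_bg_b:
            bg_chrom = rng.choice(len(chrom_names), size=n_bg_b, p=nuc_weights)
            bg_start = (rng.uniform(0, sizes[bg_chrom] - s[j : j + n_bg_b] - 1)).astype(np.int64)
            # background stays outside peaks (rejection), so a cell's FRiP
            # is its design value, not design + accidental overlap
            for _round in range(50):
                bad = np.zeros(n_bg_b, dtype=bool)
                for code in np.unique(bg_chrom):
                    mask = bg_chrom == code
                    in_ch = peak_chrom == code
                    if not in_ch.any():
                        continue
                    p_s, p_e = peak_start[in_ch], peak_end[in_ch]
                    st = bg_start[mask]
                    en = st + s[j : j + n_bg_b][mask]
                    lo = np.searchsorted(p_e, st, side="right")
                    hi = np.searchsorted(p_s, en, side="left") - 1
                    bad[mask] = hi >= lo
                if not bad.any():
                    break
                bg_start[bad] = (
                    rng.uniform(0, sizes[bg_chrom[bad]] - s[j : j + n_bg_b][bad] - 1)
                ).astype(np.int64)
            c[j : j + n_bg_b] = bg_chrom
            a[j : j + n_bg_b] = bg_start
            j += n_bg_b
        if n_mt_b:
            c[j:] = mt_code
            a[j:] = rng.uniform(0, MT_SIZE - s[j:] - 1).astype(np.int64)
        e = a + s
        chroms = np.concatenate([chroms, c])
        starts = np.concatenate([starts, a])
        ends = np.concatenate([ends, e])
        # pack (chrom, start, size) into one int64 key: sizes < 2^12, starts < 2^40
        keys = (chroms << 52) | (starts << 12) | (ends - starts)
        _, keep = np.unique(keys, return_index=True)
        keep.sort()
        chroms, starts, ends = chroms[keep], starts[keep], ends[keep]
        need = L - len(chroms)
        if need <= 0:
            break
    if len(chroms) < L:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not build a library of distinct fragments")
    perm = rng.permutation(L)
    return chroms[perm], starts[perm], ends[perm]


def simulate_cells(
    genome: SyntheticGenome,
    designs: Sequence[CellDesign],
    seed: int = 0,
    eps: float = 0.02,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sequencing: t reads drawn with replacement per cell.

    Returns the duplicate-containing fragment table (deduplication is
    downstream's job) and a per-cell truth table. ``eps`` is the leak
    rate of peak-targeted fragments into peaks closed for the cluster.
    """
    if len(designs) == 0:
        raise ValueError("no cell designs given")
    chrom_names = list(genome.chrom_sizes)
    frames = {}
    truth_rows = []
    for i, design in enumerate(designs):
        rng = np.random.default_rng([seed, 2, i])
        c, s, e = _build_library(genome, design, rng, eps)
        t = design.depth
        if t > 0:
            draw = rng.integers(0, design.library_size, size=t)
            dc, ds, de = c[draw], s[draw], e[draw]
            order = np.lexsort((de, ds, dc))  # fragments sorted within the cell
            frames[design.cell_id] = pd.DataFrame(
                {
                    "chrom": pd.Categorical.from_codes(dc[order], categories=chrom_names),
                    "start": ds[order],
                    "end": de[order],
                    "cell_id": design.cell_id,
                }
            )
        truth_rows.append(
            (
                design.cell_id,
                design.cluster,
                design.species,
                design.is_negative,
                design.library_size,
                design.depth,
                design.mt_rate,
                design.frip,
            )
        )
    if frames:
        fragments = pd.concat(
            [frames[c] for c in sorted(frames)], ignore_index=True
        )
    else:
        fragments = pd.DataFrame(columns=["chrom", "start", "end", "cell_id"])
    fragments["is_mt"] = (fragments["chrom"] == genome.mt_chrom).to_numpy(dtype=bool)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cell_id",
            "cluster",
            "species",
            "is_negative",
            "library_size",
            "depth",
            "mt_rate",
            "frip",
        ],
    )
    return fragments, truth


# ------------------------------------------------------------------ plate
def simulate_species_plate(
    n_wells: int = 384,
    doublet_rate: float = 0.013,
    seed: int = 0,
    neg_fraction: float = 0.02,
    singlet_purity: float = 0.995,
    doublet_mix: Tuple[float, float] = (0.4, 0.6),
    median_reads: int = 100_000,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """A barnyard plate: per-well species read counts plus truth.

    Wells are human or mouse singlets with equal prior, doublets with
    probability ``doublet_rate``, and a ``neg_fraction`` of near-empty
    negative controls (100-1000 total reads). Singlets draw
    ``singlet_purity`` of their reads from their own species; doublets a
    uniform mix in ``doublet_mix``.
    """
    if n_wells <= 0:
        raise ValueError("n_wells must be positive")
    if not (0 <= doublet_rate < 1):
        raise ValueError("doublet_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, 3])
    n_neg = int(round(neg_fraction * n_wells))
    neg_wells = set(rng.choice(n_wells, size=n_neg, replace=False))

    rows, truth_rows = [], []
    for w in range(n_wells):
        well_id = f"well_{w:03d}"
        if w in neg_wells:
            total = int(rng.integers(100, 1_001))
            mapped_frac = float(rng.uniform(0.2, 0.8))
            n_mapped = int(round(total * mapped_frac))
            h = int(rng.binomial(n_mapped, 0.5))
            rows.append((well_id, h, n_mapped - h, total, mapped_frac))
            truth_rows.append((well_id, "negative"))
            continue
        is_doublet = rng.random() < doublet_rate
        species = "doublet" if is_doublet else ("human" if rng.random() < 0.5 else "mouse")
        total = int(round(median_reads * math.exp(rng.normal(0, 0.5))))
        mapped_frac = float(rng.uniform(0.93, 0.99))
        n_mapped = int(round(total * mapped_frac))
        if species == "doublet":
            human_frac = float(rng.uniform(*doublet_mix))
        elif species == "human":
            human_frac = singlet_purity
        else:
            human_frac = 1.0 - singlet_purity
        h = int(rng.binomial(n_mapped, human_frac))
        rows.append((well_id, h, n_mapped - h, total, mapped_frac))
        truth_rows.append((well_id, species))
    wells = pd.DataFrame(
        rows, columns=["well_id", "human_reads", "mouse_reads", "total_reads", "mapped_fraction"]
    )
    truth = pd.DataFrame(truth_rows, columns=["well_id", "species"])
    return wells, truth


# -------------------------------------------------------------- sequences
def emit_peak_sequences(genome: SyntheticGenome, seed: int = 0) -> Dict[str, str]:
    """Uniform-background sequence per peak; planted consensus instances.

    Peaks listed in the genome's motif plan carry one exact consensus
    instance of their motif at a random offset. Deterministic per seed.
    """
    if not genome.motif_plan:
        raise ValueError("genome has no motif plan")
    rng = np.random.default_rng([seed, 4])
    planted: Dict[str, str] = {}
    for motif_name, peak_names in genome.motif_plan.items():
        for p in peak_names:
            planted[p] = motif_name
    bases = np.array(list("ACGT"))
    sequences: Dict[str, str] = {}
    for iv in genome.peaks:
        seq = bases[rng.integers(0, 4, size=iv.length)]
        if iv.name in planted:
            motif = genome.motifs[planted[iv.name]]
            if motif.width > iv.length:
                raise ValueError(f"motif {motif.name} longer than peak {iv.name}")
            offset = int(rng.integers(0, iv.length - motif.width + 1))
            seq[offset : offset + motif.width] = list(motif.consensus)
        sequences[iv.name] = "".join(seq)
    return sequences


# -------------------------------------------------------------- reference
def make_reference_profiles(
    genome: SyntheticGenome, depth: int = 200_000, seed: int = 0, background: float = 0.05
) -> pd.DataFrame:
    """Bulk accessibility references, one sample per cluster.

    Sample ``ref_c`` spreads ``depth`` counts multinomially over the
    peaks open in cluster c, with a ``background`` share spread over all
    peaks; used as the correlation target for cluster annotation.
    """
    rng = np.random.default_rng([seed, 5])
    n_peaks = len(genome.peaks)
    out = {}
    for c in range(genome.n_clusters):
        p = genome.truth[:, c].astype(float)
        p = (1 - background) * p / p.sum() + background / n_peaks
        p = p / p.sum()
        out[f"ref_{c}"] = rng.multinomial(depth, p)
    return pd.DataFrame(out, index=genome.peak_names)
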