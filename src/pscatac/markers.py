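"""Cluster marker peaks and transcription-factor motif enrichment.

Marker extraction trains a one-vs-rest L2-regularised logistic
regression on the binarized peak-by-cell matrix with the cluster labels
as targets, then ranks peaks per cluster by descending signed
coefficient — positive weight means openness of the peak votes for the
cluster — keeping the top 500 by default. Marker signal is visualised as
row-wise z-scores of log1p counts-per-million across cells ordered by
cluster.

Motif analysis scans peak sequences with log-odds position weight
matrices on both strands (``N`` scores 0, the background expectation);
a peak is a motif hit when any window reaches the score threshold
(default 80% of the consensus score). Per-cluster enrichment of a motif
in the marker peaks is an exact binomial upper tail
P(X >= k | n, p0), where n is the number of marker peaks, k how many of
them contain a hit, and p0 the hit rate among background peaks (default:
all non-marker peaks of the cluster). Benjamini-Hochberg q-values are
reported across the motif-by-cluster grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binom
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests  # BH correction

from .matrix import AccessibilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fit_marker_classifier",
    "top_marker_peaks",
    "ZscoreMatrix",
    "zscore_matrix",
    "MotifModel",
    "scan_motifs",
    "binomial_pvalue",
    "motif_enrichment",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


# ------------------------------------------------------------- classifier
def fit_marker_classifier(
    matrix: AccessibilityMatrix,
    labels: Sequence[int],
    regularisation: float = 1.0,
    seed: int = 0,
    max_iter: int = 500,
) -> pd.DataFrame:
    """One-vs-rest logistic regression of cluster identity on open peaks.

    Returns a (clusters x peaks) coefficient frame. ``regularisation``
    is the inverse L2 penalty strength (sklearn's C). Deterministic for
    a fixed seed; non-convergence is logged, not raised.
    """
    labels = np.asarray(labels)
    if len(labels) != len(matrix.cell_ids):
        raise ValueError("labels must cover every cell")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("marker extraction needs at least 2 clusters")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 cells")

    X = matrix.binarized.T.tocsr().astype(float)  # cells x peaks
    coef = np.zeros((len(clusters), X.shape[1]))
    for i, c in enumerate(clusters):
        y = (labels == c).astype(int)
        model = LogisticRegression(  # default penalty is L2
            C=regularisation,
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(X, y)
            except ConvergenceWarning:
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
                logger.warning(
                    "cluster %s: logistic fit did not converge in %d iterations",
                    c,
                    max_iter,
                )
        coef[i] = model.coef_[0]
    return pd.DataFrame(coef, index=clusters, columns=matrix.peak_ids)


def top_marker_peaks(
    coefficients: pd.DataFrame, top_n: int = 500
) -> Dict[int, List[str]]:
    """Per-cluster marker lists: peaks by descending signed coefficient.

    Ties break by peak identifier; clusters with fewer than ``top_n``
    peaks return the full ranking.
    """
    if not np.isfinite(coefficients.to_numpy()).all():
        raise ValueError("non-finite coefficients")
    out: Dict[int, List[str]] = {}
    for cluster in coefficients.index:
        row = coefficients.loc[cluster]
        order = sorted(row.index, key=lambda p: (-row[p], p))
        out[cluster] = order[: min(top_n, len(order))]
    return out


# ---------------------------------------------------------------- z-score
@dataclass
class ZscoreMatrix:
    """Row-z-scored marker signal for heatmap display.

    Rows are the concatenated per-cluster marker peaks; columns are cells
    ordered by cluster label. Constant rows are zeroed and listed in
    ``flagged_rows``.
    """

    values: pd.DataFrame
    row_cluster: pd.Series  # marker row -> source cluster
    cell_order: List[str]
    cell_labels: np.ndarray
    flagged_rows: List[str]


def zscore_matrix(
    matrix: AccessibilityMatrix,
    labels: Sequence[int],
    marker_lists: Mapping[int, Sequence[str]],
) -> ZscoreMatrix:
    """Z-scores of log1p CPM for marker peaks, cells ordered by cluster."""
    labels = np.asarray(labels)
    peak_index = {p: i for i, p in enumerate(matrix.peak_ids)}
    order = np.argsort(labels, kind="stable")
    cell_order = [matrix.cell_ids[i] for i in order]

    dense = matrix.counts.toarray().astype(float)
    col_tot = dense.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    norm = np.log1p(dense / col_tot * 1e6)

    rows = []
    row_ids = []
    row_cluster = []
    for cluster in sorted(marker_lists):
        for p in marker_lists[cluster]:
            if p not in peak_index:
                raise ValueError(f"marker peak {p!r} not in matrix")
            rows.append(norm[peak_index[p], order])
            row_ids.append(f"{cluster}:{p}")
            row_cluster.append(cluster)
    arr = np.asarray(rows)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flagged = [row_ids[i] for i in np.where(sd.ravel() == 0)[0]]
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    z[np.asarray([rid in set(flagged) for rid in row_ids])] = 0.0
    return ZscoreMatrix(
        values=pd.DataFrame(z, index=row_ids, columns=cell_order),
        row_cluster=pd.Series(row_cluster, index=row_ids),
        cell_order=cell_order,
        cell_labels=labels[order],
        flagged_rows=flagged,
    )


# ------------------------------------------------------------------ motif
@dataclass
class MotifModel:
    """A position weight matrix with a log-odds hit threshold."""

    name: str
    pfm: np.ndarray  # (4, width), counts or probabilities, A/C/G/T rows
    pseudocount: float = 0.5
    background: np.ndarray = None  # type: ignore[assignment]
    threshold: Optional[float] = None  # default: 80% of consensus score

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        probs = self.pfm + self.pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.probs = probs
        self.logodds = np.log2(probs / self.background[:, None])
        self.consensus_score = float(self.logodds.max(axis=0).sum())
        if self.threshold is None:
            self.threshold = 0.8 * self.consensus_score
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.logodds.argmax(axis=0))


def _encode(seq: str) -> np.ndarray:
    return np.asarray([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int64)


def _strand_scores(code: np.ndarray, lookup: np.ndarray, width: int) -> np.ndarray:
    n = len(code)
    if n < width:
        return np.zeros(0)
    scores = np.zeros(n - width + 1)
    for i in range(width):
        scores += lookup[code[i : i + n - width + 1], i]
    return scores


def scan_motifs(sequences: Mapping[str, str], motif: MotifModel) -> pd.Series:
    """Count motif hits per sequence, both strands.

    A hit is any window whose log-odds score reaches the motif threshold;
    ``N`` bases contribute 0 (the background expectation).
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    width = motif.width
    lookup = np.vstack([motif.logodds, np.zeros((1, width))])  # row 4 = N
    counts = {}
    for name, seq in sequences.items():
        if len(seq) < width:
            raise ValueError(f"sequence {name!r} shorter than motif width {width}")
        code = _encode(seq)
        rc = 3 - code[::-1]
        rc[code[::-1] == 4] = 4
        fwd = _strand_scores(code, lookup, width)
        rev = _strand_scores(rc, lookup, width)
        counts[name] = int((fwd >= motif.threshold).sum() + (rev >= motif.threshold).sum())
    return pd.Series(counts, name=motif.name)


# ------------------------------------------------------------- enrichment
def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def motif_enrichment(
    hit_table: pd.DataFrame,
    marker_lists: Mapping[int, Sequence[str]],
    background: Union[str, float, Mapping[int, Sequence[str]]] = "complement",
    adjust: bool = True,
) -> pd.DataFrame:
    """Binomial enrichment of each motif in each cluster's marker peaks.

    ``hit_table`` is peaks x motifs (hit counts from :func:`scan_motifs`).
    ``background`` is either ``"complement"`` (all peaks not in the
    cluster's marker list), a fixed hit rate, or an explicit per-cluster
    peak list. Returns a long frame with columns motif, cluster, n, k,
    p0, p (and BH-adjusted q when ``adjust``). A zero background rate
    with k > 0 is reported as p = 0 and flagged degenerate.
    """
    has_hit = hit_table >= 1
    rows = []
    for cluster in sorted(marker_lists):
        markers = list(marker_lists[cluster])
        if len(markers) == 0:
            raise ValueError(f"cluster {cluster}: empty marker list")
        missing = set(markers) - set(hit_table.index)
        if missing:
            raise ValueError(f"marker peaks missing from hit table: {sorted(missing)[:3]}")
        for motif in hit_table.columns:
            n = len(markers)
            k = int(has_hit.loc[markers, motif].sum())
            degenerate = False
            if isinstance(background, str) and background == "complement":
                bg_peaks = hit_table.index.difference(markers)
                if len(bg_peaks) == 0:
                    raise ValueError("no background peaks left after removing markers")
                p0 = float(has_hit.loc[bg_peaks, motif].mean())
            elif isinstance(background, Mapping):
                bg_peaks = list(background[cluster])
                p0 = float(has_hit.loc[bg_peaks, motif].mean())
            else:
                p0 = float(background)
            if p0 == 0.0:
                p = 0.0 if k > 0 else 1.0
                degenerate = k > 0
                if degenerate:
                    logger.warning(
                        "motif %s cluster %s: zero background hit rate with k=%d",
                        motif,
                        cluster,
                        k,
                    )
            else:
                p = binomial_pvalue(k, n, min(p0, 1.0))
            rows.append((motif, cluster, n, k, p0, p, degenerate))
    out = pd.DataFrame(
        rows, columns=["motif", "cluster", "n", "k", "p0", "p", "degenerate_background"]
    )
    if adjust:
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
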