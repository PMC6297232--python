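"""Latent semantic indexing of binarized accessibility, and clustering.

The binarized peak-by-cell matrix is weighted by TF-IDF,

    w(i, j) = [ b(i, j) / colsum(j) ] * log(1 + C / df(i)),

where C is the number of cells and df(i) the number of cells in which
peak i is open, then factored by truncated SVD. The first singular
dimension predominantly tracks per-cell sequencing depth (number of open
peaks) and is dropped by default; dimensions 2..n_svd are the embedding
passed to clustering and visualisation. The depth association of
dimension 1 is reported as a diagnostic (Spearman correlation with log
depth).

Clustering is spectral: a symmetrized k-nearest-neighbour connectivity
graph on the embedding, normalised-Laplacian spectral embedding, and
seeded k-means, with labels renumbered by decreasing cluster size.
Pseudo-bulk profiles (column sums within a cluster) are compared to
reference bulk accessibility by Pearson correlation of log1p
counts-per-million over a shared peak set, and each cluster is annotated
with its best-correlated reference sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import kneighbors_graph

from .matrix import AccessibilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TfidfMatrix",
    "tfidf",
    "LsiEmbedding",
    "lsi_embed",
    "spectral_cluster",
    "pseudo_bulk",
    "ClusterAnnotation",
    "annotate_clusters",
]


@dataclass
class TfidfMatrix:
    """TF-IDF-weighted binary accessibility (peaks x cells)."""

    weights: sp.csr_matrix
    peak_ids: list
    cell_ids: list
    depth: np.ndarray  # open peaks per cell (binarized column sums)
    idf: np.ndarray


def tfidf(matrix: AccessibilityMatrix) -> TfidfMatrix:
    """TF-IDF weighting of the binarized matrix.

    All-zero cells are dropped with a warning (their term frequency is
    undefined); peaks open in no cell are dropped. Duplicating a cell's
    raw counts changes nothing: only the binarized pattern enters.
    """
    b = matrix.binarized.astype(float)
    if b.shape[0] == 0 or b.shape[1] == 0:
        raise ValueError("empty matrix")
    depth = np.asarray(b.sum(axis=0)).ravel()
    keep_cells = depth > 0
    if not keep_cells.all():
        logger.warning("dropping %d all-zero cells before TF-IDF", (~keep_cells).sum())
        b = b[:, keep_cells]
        depth = depth[keep_cells]
    if b.shape[1] == 0:
        raise ValueError("no non-empty cells")
    df = np.asarray(b.sum(axis=1)).ravel()
    keep_peaks = df > 0
    if not keep_peaks.all():
        b = b[keep_peaks, :]
        df = df[keep_peaks]
    n_cells = b.shape[1]
    idf = np.log1p(n_cells / df)
    tf = b @ sp.diags(1.0 / depth)
    weights = sp.diags(idf) @ tf
    return TfidfMatrix(
        weights=sp.csr_matrix(weights),
        peak_ids=[p for p, k in zip(matrix.peak_ids, keep_peaks) if k],
        cell_ids=[c for c, k in zip(matrix.cell_ids, keep_cells) if k],
        depth=depth,
        idf=idf,
    )


@dataclass
class LsiEmbedding:
    """Truncated-SVD embedding of TF-IDF accessibility.

    ``coords`` holds dimensions 2..n_svd (cells x (n_svd - 1)) when the
    depth dimension is dropped, the full n_svd otherwise. ``dim1`` is
    always kept for diagnostics.
    """

    cell_ids: list
    coords: np.ndarray
    dim1: np.ndarray
    singular_values: np.ndarray
    depth: np.ndarray
    dim1_depth_corr: float
    drop_first: bool


def lsi_embed(
    tf: TfidfMatrix,
    n_svd: int = 50,
    drop_first: bool = True,
    seed: int = 0,
    l2_norm: bool = True,
) -> LsiEmbedding:
    """Truncated SVD of the TF-IDF matrix; cell coordinates U·S.

    Each cell vector is L2-normalised before the factorisation (the
    convention of scikit-learn's TF-IDF transformer): the projection of a
    unit cell vector on the leading all-positive component then grows
    with the number of open peaks, which is what makes dimension 1 a
    clean per-cell depth axis. Signs are fixed by making each
    component's largest-magnitude peak loading positive, so a given seed
    is bitwise reproducible. If ``n_svd`` exceeds what the matrix
    supports, fewer components are returned with a warning.
    """
    X = tf.weights.T.tocsr()  # cells x peaks
    if l2_norm:
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        norms[norms == 0] = 1.0
        X = sp.diags(1.0 / norms) @ X
    max_k = min(X.shape) - 1
    k = min(n_svd, max_k)
    if k < n_svd:
        logger.warning("n_svd=%d exceeds matrix rank budget; using %d", n_svd, k)
    if k < 2:
        raise ValueError("need at least 2 SVD dimensions")
    svd = TruncatedSVD(n_components=k, algorithm="arpack", random_state=seed)
    coords = svd.fit_transform(X)  # U * S
    # deterministic sign convention: largest |loading| positive per component
    for comp in range(k):
        j = int(np.argmax(np.abs(svd.components_[comp])))
        if svd.components_[comp, j] < 0:
            coords[:, comp] *= -1.0
    corr = spearmanr(coords[:, 0], np.log(tf.depth)).statistic
    kept = coords[:, 1:] if drop_first else coords
    return LsiEmbedding(
        cell_ids=list(tf.cell_ids),
        coords=kept,
        dim1=coords[:, 0],
        singular_values=svd.singular_values_.copy(),
        depth=tf.depth.copy(),
        dim1_depth_corr=float(corr),
        drop_first=drop_first,
    )


def _bridge_components(affinity: sp.csr_matrix, coords: np.ndarray) -> sp.csr_matrix:
    """Connect a disconnected kNN graph by joining nearest cross-component pairs."""
    affinity = sp.lil_matrix(affinity)
    while True:
        n_comp, labels = connected_components(sp.csr_matrix(affinity), directed=False)
        if n_comp == 1:
            break
        logger.warning("affinity graph has %d components; bridging", n_comp)
        a = np.where(labels == labels[0])[0]
        b = np.where(labels != labels[0])[0]
        d = cdist(coords[a], coords[b])
        i, j = np.unravel_index(np.argmin(d), d.shape)
        affinity[a[i], b[j]] = affinity[b[j], a[i]] = 1.0
    return sp.csr_matrix(affinity)


def spectral_cluster(
    embedding: LsiEmbedding,
    k: int,
    seed: int = 0,
    knn: int = 15,
) -> np.ndarray:
    """Spectral clustering of the LSI embedding into k groups.

    Returns integer labels 0..k-1 renumbered by decreasing cluster size
    (ties by first occurrence), aligned with ``embedding.cell_ids``.
    """
    n = embedding.coords.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}]")
    knn = min(knn, n - 1)
    A = kneighbors_graph(embedding.coords, n_neighbors=knn, mode="connectivity")
    A = 0.5 * (A + A.T)
    A = _bridge_components(sp.csr_matrix(A), embedding.coords)
    model = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    raw = model.fit_predict(A)
    return _relabel_by_size(raw)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    values, counts = np.unique(labels, return_counts=True)
    first_seen = {v: int(np.argmax(labels == v)) for v in values}
    order = sorted(values, key=lambda v: (-counts[list(values).index(v)], first_seen[v]))
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[v] for v in labels], dtype=np.int64)


def pseudo_bulk(matrix: AccessibilityMatrix, labels: Sequence[int]) -> pd.DataFrame:
    """Merge cells within each cluster: cluster-by-peak summed counts.

    Total mass is conserved exactly; cell order within a cluster is
    irrelevant.
    """
    labels = np.asarray(labels)
    if len(labels) != len(matrix.cell_ids):
        raise ValueError("labels must cover every cell")
    clusters = np.unique(labels)
    out = np.zeros((len(clusters), len(matrix.peak_ids)), dtype=np.int64)
    csc = matrix.counts.tocsc()
    for i, c in enumerate(clusters):
        cols = np.where(labels == c)[0]
        out[i] = np.asarray(csc[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=clusters, columns=matrix.peak_ids)


@dataclass
class ClusterAnnotation:
    """Cluster-to-reference assignment by accessibility correlation."""

    correlations: pd.DataFrame  # clusters x reference samples
    assignment: pd.Series  # cluster -> best reference sample
    tied: pd.Series  # cluster -> bool, argmax tie broken by name


def _log_cpm(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total == 0:
        return np.zeros_like(v, dtype=float)
    return np.log1p(v / total * 1e6)


def annotate_clusters(
    pseudo_bulk_counts: pd.DataFrame, reference: pd.DataFrame
) -> ClusterAnnotation:
    """Correlate cluster pseudo-bulks with reference bulk profiles.

    Both tables must be indexed on the same reference peak set
    (pseudo-bulk columns = reference rows = peak ids). Pearson
    correlation of log1p CPM; zero-variance vectors yield undefined
    correlations that are excluded from the argmax; exact ties resolve to
    the lexicographically smaller sample name and are flagged.
    """
    if set(pseudo_bulk_counts.columns) != set(reference.index):
        raise ValueError("pseudo-bulk and reference must share the same peak set")
    ref = reference.loc[list(pseudo_bulk_counts.columns)]
    samples = sorted(ref.columns)
    ref_t = {s: _log_cpm(ref[s].to_numpy(dtype=float)) for s in samples}

    corr = pd.DataFrame(index=pseudo_bulk_counts.index, columns=samples, dtype=float)
    for cluster in pseudo_bulk_counts.index:
        v = _log_cpm(pseudo_bulk_counts.loc[cluster].to_numpy(dtype=float))
        for s in samples:
            w = ref_t[s]
            if v.std() == 0 or w.std() == 0:
                corr.loc[cluster, s] = np.nan
            else:
                corr.loc[cluster, s] = float(pearsonr(v, w).statistic)

    assignment = {}
    tied = {}
    for cluster in corr.index:
        row = corr.loc[cluster].dropna()
        if row.empty:
            raise ValueError(f"no defined correlations for cluster {cluster}")
        best = row.max()
        winners = sorted(row.index[row == best])
        assignment[cluster] = winners[0]
        tied[cluster] = len(winners) > 1
    return ClusterAnnotation(
        correlations=corr,
        assignment=pd.Series(assignment),
        tied=pd.Series(tied),
    )
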