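"""Shared fixtures: a synthetic genome and the standard 4-cluster dataset.

The heavyweight fixtures are session-scoped so the embedding/clustering/
marker tests reuse one simulation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pscatac import lsi, matrix as mx, qc, synth

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SEED = 11


@pytest.fixture(scope="session")
def genome():
    return synth.make_genome(seed=SEED)


@pytest.fixture(scope="session")
def small_genome():
    return synth.make_genome(
        n_chroms=1, n_peaks=60, n_clusters=3, n_specific=10, seed=SEED
    )


@pytest.fixture(scope="session")
def default_dataset(genome):
    """4 clusters x 75 cells on 1,200 peaks, depth varying 10x."""
    designs = synth.default_designs(genome, cells_per_cluster=75, seed=SEED)
    fragments, truth = synth.simulate_cells(genome, designs, seed=SEED)
    dedup = qc.dedup(fragments)
    counts = mx.count_matrix(dedup[~dedup["is_mt"]], genome.peaks)
    return {
        "genome": genome,
        "designs": designs,
        "fragments": fragments,
        "truth": truth,
        "dedup": dedup,
        "matrix": counts,
    }


@pytest.fixture(scope="session")
def default_embedding(default_dataset):
    tf = lsi.tfidf(default_dataset["matrix"])
    return lsi.lsi_embed(tf, n_svd=50, seed=SEED)


@pytest.fixture(scope="session")
def default_labels(default_dataset, default_embedding):
    return lsi.spectral_cluster(default_embedding, k=4, seed=SEED)


def majority_cluster_map(labels, cell_ids, truth):
    """Map each predicted label to the majority true cluster (must be a bijection)."""
    tmap = truth.set_index("cell_id")["cluster"]
    true = np.asarray([tmap[c] for c in cell_ids])
    mapping = {}
    for lab in np.unique(labels):
        vals, counts = np.unique(true[labels == lab], return_counts=True)
        mapping[int(lab)] = int(vals[np.argmax(counts)])
    assert sorted(mapping.values()) == sorted(set(true)), "label->truth map not a bijection"
    return mapping
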