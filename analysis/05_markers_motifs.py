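#!/usr/bin/env python
"""Marker peaks per cluster and motif enrichment in them.

Trains the one-vs-rest logistic classifier on the binarized matrix with
the spectral-cluster labels, extracts each cluster's top-500 marker
peaks, summarises their z-score signal, assigns nearest genes, scans the
peak sequences with the planted PWMs and tests binomial enrichment.

Run after 04_lsi_clustering.py:  python analysis/05_markers_motifs.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pscatac import io as pio
from pscatac import markers, synth
from pscatac.matrix import annotate_peaks

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

data = Path("scratch/data")
results = Path("results")

matrix = pio.read_matrix(data / "counts")
labels = pd.read_csv(results / "cluster_labels.tsv", sep="\t")
labels = labels.set_index("cell_id").loc[matrix.cell_ids, "cluster"].to_numpy()
genome = synth.make_genome(seed=args.seed)

print("== one-vs-rest logistic marker extraction ==")
coef = markers.fit_marker_classifier(matrix, labels, seed=args.seed)
tops = markers.top_marker_peaks(coef, top_n=500)
for c, top in tops.items():
    planted = set()
    for truth_cluster, peaks_ in genome.cluster_specific.items():
        overlap = len(set(peaks_) & set(top))
        if overlap > len(planted):
            planted = set(peaks_) & set(top)
            best = truth_cluster
    print(f"  cluster {c}: {len(planted)}/100 planted peaks of truth cluster {best} "
          "in its top 500")

print("== nearest genes of the top-50 markers ==")
tss = pio.read_bed(data / "tss.bed")
annotation = annotate_peaks(genome.peaks, tss).set_index("peak_id")
rows = []
for c, top in tops.items():
    for rank, p in enumerate(top[:50], start=1):
        rows.append((c, rank, p, float(coef.loc[c, p]), annotation.loc[p, "gene"],
                     annotation.loc[p, "category"]))
marker_table = pd.DataFrame(
    rows, columns=["cluster", "rank", "peak_id", "coefficient", "gene", "category"]
)
marker_table.to_csv(results / "marker_peaks_top50.tsv", sep="\t", index=False)
print(marker_table.groupby("cluster")["category"].value_counts().to_string())

print("== z-score signal of the markers ==")
z = markers.zscore_matrix(matrix, labels, tops)
inside = []
for rid in z.values.index:
    lab = z.row_cluster[rid]
    vals = z.values.loc[rid].to_numpy()
    inside.append(vals[z.cell_labels == lab].mean())
print(f"  mean within-cluster z across {len(inside)} marker rows: {np.mean(inside):.2f}")

print("== motif scan + binomial enrichment ==")
sequences = pio.read_fasta(data / "peak_sequences.fa")
hit_table = pd.DataFrame(
    {name: markers.scan_motifs(sequences, m) for name, m in genome.motifs.items()}
)
enrich = markers.motif_enrichment(hit_table, tops)
enrich.to_csv(results / "motif_enrichment.tsv", sep="\t", index=False)
planted_by_cluster = {c: m for m, c in genome.motif_cluster.items()}
for lab in sorted(tops):
    sub = enrich[enrich["cluster"] == lab].sort_values(["p", "motif"])
    best = sub.iloc[0]
    print(f"  cluster {lab}: top motif {best['motif']} "
          f"(k={best['k']}/{best['n']}, p0={best['p0']:.3f}, p={best['p']:.3g})")
print("wrote results/marker_peaks_top50.tsv and results/motif_enrichment.tsv")
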