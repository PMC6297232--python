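#!/usr/bin/env python
"""Generate the synthetic study data every later step consumes.

Builds the 4-cluster synthetic genome (1,200 peaks, 100 cluster-specific
peaks per cluster, planted motifs), a 300-cell panel with 10x depth
variation, a deep-sequenced 20-cell panel at the ~95%-duplication regime,
and a 384-well species-mixing plate. Large fragment tables go to
scratch/data; small truth tables and BED/FASTA references to scratch/data
as well (everything here is regenerable from the seed).

Run from the repository root:  python analysis/01_simulate_data.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np

from pscatac import io as pio
from pscatac import synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path("scratch/data")
out.mkdir(parents=True, exist_ok=True)

print("== synthetic genome ==")
genome = synth.make_genome(seed=args.seed)
print(f"peaks: {len(genome.peaks)}  TSS: {len(genome.tss)}  clusters: {genome.n_clusters}")
pio.write_bed(genome.peaks, out / "peaks.bed")
pio.write_bed(genome.tss, out / "tss.bed")
np.save(out / "truth_matrix.npy", genome.truth)

print("== main 300-cell panel (depth varying 10x, independent of cluster) ==")
designs = synth.default_designs(genome, cells_per_cluster=75, seed=args.seed)
fragments, truth = synth.simulate_cells(genome, designs, seed=args.seed)
fragments = fragments.assign(chrom=fragments["chrom"].astype(str))
pio.write_fragments(fragments, out / "fragments.tsv.gz")
truth.to_csv(out / "cell_truth.tsv", sep="\t", index=False)
print(f"cells: {truth.shape[0]}  fragment records: {len(fragments):,}")

print("== deep-sequenced panel (t = 20 L, the study's saturation regime) ==")
rng = np.random.default_rng([args.seed, 10])
deep = [
    synth.CellDesign(
        f"deep_{i:02d}", int(rng.integers(0, genome.n_clusters)),
        library_size=(L := int(rng.uniform(20_000, 45_000))), depth=20 * L,
    )
    for i in range(20)
]
deep_frags, deep_truth = synth.simulate_cells(genome, deep, seed=args.seed)
deep_frags = deep_frags.assign(chrom=deep_frags["chrom"].astype(str))
pio.write_fragments(deep_frags, out / "fragments_deep.tsv.gz")
deep_truth.to_csv(out / "cell_truth_deep.tsv", sep="\t", index=False)
print(f"cells: 20  fragment records: {len(deep_frags):,}")

print("== species-mixing plate ==")
wells, plate_truth = synth.simulate_species_plate(
    n_wells=384, doublet_rate=0.013, seed=args.seed, neg_fraction=0.02
)
wells.to_csv(out / "plate_wells.tsv", sep="\t", index=False)
plate_truth.to_csv(out / "plate_truth.tsv", sep="\t", index=False)
print(plate_truth["species"].value_counts().to_string())

print("== peak sequences with planted motif instances ==")
sequences = synth.emit_peak_sequences(genome, seed=args.seed)
pio.write_fasta(sequences, out / "peak_sequences.fa")
print(f"wrote {len(sequences)} peak sequences; motifs: {sorted(genome.motifs)}")
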