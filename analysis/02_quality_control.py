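#!/usr/bin/env python
"""Per-cell QC of the simulated panels.

Computes total/unique reads, duplication, MT content, FRiP and the
Lander-Waterman library-size estimate per cell; checks the technical
cutoff; profiles insert sizes and TSS enrichment; and traces the
saturation curve of a deep cell. Writes per-cell tables and a JSON
summary under results/.

Run after 01_simulate_data.py:  python analysis/02_quality_control.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pscatac import io as pio
from pscatac import qc

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

data = Path("scratch/data")
results = Path("results")
results.mkdir(exist_ok=True)

peaks = pio.read_bed(data / "peaks.bed")
tss = pio.read_bed(data / "tss.bed")

print("== deep panel: the study-like sequencing regime ==")
deep = pio.read_fragments(data / "fragments_deep.tsv.gz")
table = qc.cell_qc(deep, peaks)
table.to_csv(results / "qc_cells_deep.tsv", sep="\t", index=False)
summary = {
    "n_cells": int(len(table)),
    "median_total_reads": float(table["total_reads"].median()),
    "median_unique_fragments": float(table["unique_fragments"].median()),
    "median_duplication_rate": float(table["duplication_rate"].median()),
    "median_mt_fraction": float(table["mt_fraction"].median()),
    "median_frip": float(table["frip"].median()),
    "median_est_library_size": float(table["est_library_size"].median()),
}
for k, v in summary.items():
    print(f"  {k}: {v:,.4g}")

print("== insert sizes (nucleosomal banding) ==")
hist = qc.insert_size_hist(deep)
for centre in (75, 200, 400):
    window = hist[centre - 10 : centre + 11]
    print(f"  mode near {centre} bp: max count {int(window.max()):,}")
np.savetxt(results / "insert_size_hist.tsv", hist, fmt="%d")

print("== TSS enrichment ==")
profile = qc.tss_enrichment(qc.dedup(deep), tss)
summary["tss_enrichment_score"] = float(profile.enrichment_score)
print(f"  enrichment score: {profile.enrichment_score:.2f} over {profile.n_tss} TSS")

print("== saturation of one deep cell ==")
one = deep[deep["cell_id"] == deep["cell_id"].iloc[0]]
curve = qc.saturation_curve(one, [0.05, 0.1, 0.25, 0.5, 0.75, 1.0], seed=args.seed)
curve.to_csv(results / "saturation_curve.tsv", sep="\t", index=False)
full = curve["n_unique"].iloc[-1]
quarter = float(curve.set_index("fraction").loc[0.25, "n_unique"])
summary["unique_captured_at_quarter_depth"] = quarter / full
print(curve.to_string(index=False))
print(f"  a quarter of the reads already captures {100 * quarter / full:.1f}% "
      "of the fragments seen at full depth")

print("== technical cutoff on the main panel ==")
main = pio.read_fragments(data / "fragments.tsv.gz")
main_table = qc.cell_qc(main, peaks)
main_table.to_csv(results / "qc_cells_main.tsv", sep="\t", index=False)
passed = qc.filter_cells(main_table)
summary["main_panel_cells"] = int(len(main_table))
summary["main_panel_pass_read_cutoff"] = int(passed.sum())
print(f"  {passed.sum()} / {len(main_table)} cells pass the >10,000-read cutoff "
      "(mapping rates are not simulated; that clause is skipped)")

with open(results / "qc_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print("wrote results/qc_summary.json")
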