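#!/usr/bin/env python
"""Classify the barnyard plate and measure the collision rate.

Applies the technical cutoff (>10,000 reads, >90% mapped) and the
human:mouse ratio rule (>10 human, <0.1 mouse, otherwise doublet), then
compares the calls with the generator's truth.

Run after 01_simulate_data.py:  python analysis/03_species_mixing.py
"""

import json
from pathlib import Path

import pandas as pd

from pscatac import speciesmix

data = Path("scratch/data")
results = Path("results")
results.mkdir(exist_ok=True)

wells = pd.read_csv(data / "plate_wells.tsv", sep="\t")
truth = pd.read_csv(data / "plate_truth.tsv", sep="\t")

calls = speciesmix.classify_wells(wells)
calls.to_csv(results / "speciesmix_calls.tsv", sep="\t", index=False)
summary = speciesmix.summarize_calls(calls)
rate = speciesmix.collision_rate(summary)

print("call counts:")
print(summary.to_string())
print(f"collision rate among successful wells: {100 * rate:.2f}%")

merged = calls.merge(truth, on="well_id")
passing = merged[merged["call"] != "failed"]
acc = float((passing["call"] == passing["species"]).mean())
print(f"accuracy vs truth on {len(passing)} passing wells: {100 * acc:.1f}%")
neg = merged[merged["species"] == "negative"]
print(f"negative controls failing the cutoff: {(neg['call'] == 'failed').sum()} / {len(neg)}")

with open(results / "speciesmix_summary.json", "w") as fh:
    json.dump(
        {
            **{k: int(v) for k, v in summary.items()},
            "collision_rate": rate,
            "accuracy_on_passing_wells": acc,
        },
        fh,
        indent=2,
    )
print("wrote results/speciesmix_summary.json")
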