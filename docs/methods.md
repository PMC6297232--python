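# Methods

This note documents the models behind `pscatac`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
compute.

## Fragments, deduplication and per-cell QC

The unit record is the *fragment*: the genomic interval between a read
pair's Tn5 insertion points, carried as a row of a BED-like table
(0-based, half-open coordinates throughout). Records with mapping quality
below 30 are discarded at read time when a `mapq` column is present,
mirroring the upstream `samtools -q 30` step; alignment itself is out of
scope, so mapping *rates* enter only through an optional per-cell sidecar.

Deduplication keeps one record per distinct `(cell_id, chrom, start, end)`.
Identical coordinates in different wells are distinct fragments — each well
is an independent library. Per cell we report total reads *t*, unique
fragments *u*, duplication rate 1 − *u*/*t*, mitochondrial fraction (share
of deduplicated fragments on the configured MT chromosome, default `chrM`),
and FRiP. FRiP is computed on deduplicated, **non-mitochondrial** fragments
with the any-overlap (≥ 1 bp) rule; this makes the metric comparable across
sequencing depths and keeps MT contamination from deflating it. A cell with
no non-MT fragments gets FRiP = NaN rather than being dropped.

The technical cutoff is `total_reads > 10,000 AND mapped_fraction > 0.90`,
both strict, matching the "more than" phrasing of the original rule. When
mapping rates are unavailable the second clause is skipped with a warning.

## Library complexity (Lander–Waterman)

Sequencing a library of L distinct fragments with t reads drawn uniformly
with replacement yields an expected unique count

    u = L (1 − exp(−t/L)).

`estimate_library_size(t, u)` inverts this for L by bracketed bisection
(relative tolerance 1e−9, bracket expanded upward until the sign changes).
The function is undefined (NaN) at u = t, where the root diverges. One
fragment record counts as one read pair, the same accounting Picard's
estimator uses. Tests verify agreement with an independent iteratively
refined grid search to < 1e−6 relative error and parameter recovery from
resampled libraries (median error ~0.1% at t = 3L over 200 cells).

## Species mixing

A well's call is determined by the read ratio R = human/mouse after the
technical cutoff: human if R > 10, mouse if R < 0.1, doublet otherwise, with
all boundary values resolving away from a singlet/pass call. R = +∞ when
m = 0 with h > 0 (a human call); h = m = 0 cannot pass the read cutoff, so
an undefined ratio never reaches classification. The collision rate is
doublets / (singlets + doublets) among successful wells.

## Saturation

The saturation curve subsamples each cell's reads without replacement at a
series of fractions and re-deduplicates. Subsamples are *nested* — each
fraction takes a prefix of one seeded per-cell permutation — so the curve
is monotone by construction and fraction 1.0 reproduces the full-depth
unique count exactly; a prefix of a random permutation is a uniform
without-replacement sample, so the statistics are unchanged.

## Accessibility matrix

The reference peak set is the union of the input peak sets with
bedtools-merge semantics: overlapping *or book-ended* intervals collapse;
the output is sorted and non-overlapping, which `count_matrix` requires (it
raises otherwise, forcing an explicit merge). Counting uses a binary-search
sweep per chromosome, O((n+m) log m); a deduplicated fragment increments
every peak it overlaps by ≥ 1 bp, so a fragment spanning two adjacent peaks
counts in both. Fragments (not read ends) are the counting unit — a
depth-robust choice. Binarization marks a peak open for a cell when its
count is ≥ 1.

Peak→gene annotation assigns the nearest TSS by distance from the peak
midpoint to the TSS coordinate (the BED start; `end − 1` for minus-strand
records), signed as midpoint − TSS. Categories: promoter within 1 kb,
"genic" within 10 kb (a gene-body proxy — no gene models are consulted),
distal beyond. Equidistant ties resolve to the lexicographically smaller
gene name; peaks on chromosomes without any TSS are flagged with undefined
distance.

## TF-IDF, LSI and the depth dimension

The binarized matrix B (peaks × cells) is weighted

    w(i, j) = [ B(i,j) / colsum(j) ] · log(1 + C / df(i)),

with C the number of cells and df(i) the number of cells in which peak i is
open; all-zero cells are dropped with a warning, peaks with df = 0 are
dropped. Before the SVD each cell vector is L2-normalised — the convention
of scikit-learn's TF-IDF transformer, through which this style of analysis
is usually run. This normalisation matters: on unit cell vectors the
projection onto the leading (all-positive) component grows with the number
of open peaks, so the first singular dimension becomes a clean per-cell
depth axis (|Spearman| ≈ 0.99 against log depth on the default synthetic
data), whereas with bare L1 term frequencies the depth signal largely
cancels. Dimension 1 is therefore computed, reported as a diagnostic
(`dim1_depth_corr`), and dropped by default; dimensions 2..n_svd
(n_svd = 50) are the embedding. Component signs are fixed by making each
component's largest-magnitude peak loading positive, so results are
reproducible bit-for-bit for a fixed seed (ARPACK-based truncated SVD).

## Spectral clustering

A k-nearest-neighbour connectivity graph (knn = 15) on the embedding is
symmetrized; if it is disconnected, the nearest cross-component pairs are
bridged (logged) until connected. Normalised-Laplacian spectral embedding
followed by seeded k-means assigns k clusters; labels are renumbered by
decreasing cluster size. k is a user parameter — no selection rule is
imposed; cosine distance is the natural metric on LSI coordinates and is
what the embedding-quality tests use.

## Pseudo-bulk and cluster annotation

Pseudo-bulk profiles are exact column sums of the count matrix within each
cluster (mass conserved). Annotation computes Pearson correlation between
log1p counts-per-million vectors of each (cluster, reference sample) pair
over a shared peak set; the assignment is the argmax per cluster,
zero-variance vectors yield undefined correlations that are excluded, and
exact ties resolve to the smaller sample name and are flagged.

## Marker peaks and motif enrichment

Markers come from a one-vs-rest logistic regression (L2 penalty, inverse
strength C = 1.0, lbfgs, seeded) of cluster membership on the binarized
peaks. Peaks are ranked per cluster by *signed* coefficient — markers are
cluster-open peaks, not merely discriminative ones — with ties broken by
peak id; the top 500 are kept. Marker signal is displayed as row z-scores
of log1p CPM with cells ordered by cluster; constant rows are zeroed and
flagged.

Motif models are PFMs (counts or probabilities) with pseudocount 0.5 per
base and a uniform 0.25 background; scanning scores every window on both
strands with log2 odds, `N` contributing 0 (the background expectation),
and a hit is any window reaching the threshold, by default 80% of the
consensus score. Enrichment of a motif in a cluster's n marker peaks, k of
which contain ≥ 1 hit, is the exact binomial upper tail P(X ≥ k | n, p₀)
with p₀ estimated as the hit rate among background peaks — by default the
complement of the cluster's markers within the reference peak set (no
GC/length matching). Raw p-values are reported alongside
Benjamini–Hochberg q-values across the motif × cluster grid; p₀ = 0 with
k > 0 is reported as p = 0 and flagged degenerate.

## The synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes, with full ground truth:

* **Genome**: non-overlapping 500-bp peaks with 1–3 kb gaps on a few
  chromosomes; each cluster owns a disjoint block of specific peaks (open
  only there), the remainder constitutively open. Per-peak accessibility
  strengths are heavy-tailed (log-normal, σ = 1): a few strong peaks carry
  much of the signal and weak peaks surface only at depth, as in real ATAC
  data — this frequency spectrum is what gives the depth dimension its
  bite. Every tenth peak midpoint doubles as a TSS (random strand), so TSS
  enrichment is genuine. One random PWM (width 12, dominant base 0.88) per
  cluster is planted as an exact consensus instance in each of that
  cluster's specific peaks.
* **Cells**: a latent library of exactly L distinct fragments — a fraction
  `frip` (default 0.6) targeted at peaks open for the cell's cluster
  (strength-weighted, with leak rate ε = 0.02 into closed peaks), the rest
  uniform background *rejected out of peaks* so a cell's true FRiP is its
  design value, and a fraction `mt_rate` (default 0.02) mitochondrial.
  Sequencing draws t reads with replacement from this library, so observed
  unique counts obey the Lander–Waterman relation exactly and t ≈ 20 L
  reproduces the ~95% duplication regime of a saturated plate experiment.
  Insert sizes follow a log-normal mixture centred near 75/200/400 bp
  (weights 0.55/0.30/0.15) emulating nucleosome-free/mono/di banding.
* **Default panel**: 4 clusters × 75 cells on 1,200 peaks (100 specific per
  cluster); L log-uniform over 600–6,000 (a 10× span) and t/L log-uniform
  over 3–20×, both independent of the cluster label, so depth is a pure
  nuisance axis.
* **Plates**: human/mouse singlets with equal prior (purity 0.995 by
  default), doublets at a configurable rate drawing 40–60% from each
  species, ~2% near-empty negative wells with 100–1,000 total reads, and
  log-normal well depths (median 100k reads).
* **Seeding**: all randomness flows from one integer seed; per-cell
  substreams are derived by counter, so adding cells never perturbs
  earlier ones.

What the generator does **not** emulate: real read sequences or alignment
error, GC and mappability bias, within-cluster gradients or doublets inside
a species, peak-calling noise (truth peaks are the peak set), and gene
models. Passing tests therefore demonstrate that the pipeline's inference
is correct under its own model assumptions — complexity recovery,
classification margins, depth/cluster separation, marker and motif
recovery — not that those assumptions capture every property of real
chromatin data.

## Problem sizes and degenerate inputs

The test suite and acceptance script use the default 300-cell panel, a
20-cell deep panel (t = 20 L), 200 cells for complexity recovery and a
384-well plate — sizes at which every stage's recovery target is already
stable. Degenerate cases are defined rather than crashed on: zero-fragment
cells yield zero/NaN metrics, u = t yields an undefined library size,
all-MT cells an undefined FRiP, empty flanks an undefined TSS score,
constant rows zeroed z-scores, and k = 0 motif hits a p-value of exactly 1.
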