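# Methods

This note documents the models implemented in `modfish`, the defaults and
why they were chosen, the synthetic-data generator's scope, and numerical
conventions. It is the place to look before changing a default.

## Reference preparation

A gene × cell count matrix passes quality control in a fixed order: cell
filters first (unique-gene band, default 200–3000; mitochondrial count
fraction ≤ 0.5, mitochondrial genes identified by `mt-`/`MT-` id prefix
when no explicit flags are given), then gene prevalence (expressed in
≥ 10 cells). Cell filters run before gene filters because gene prevalence
changes when cells are removed. QC is idempotent in practice but not by
construction: removing genes lowers per-cell unique-gene counts, so a
second pass can in principle remove further cells when a cell sits exactly
at the threshold; the test suite exercises idempotence on data with margin.

Three views are derived: `cell_scaled` (each cell scaled to 10 000 total
counts) feeds the signal model; `log_view` (natural log, pseudo-count 1)
feeds DE and gene-gene correlation; `gene_scaled` standardizes each gene
of the log view to mean 0 and unit sample variance (n − 1; constant genes
map to 0) for dimensionality reduction. DE markers are one-vs-rest,
ranked by log fold-change (ties broken lexicographically for determinism)
with a Wilcoxon rank-sum p reported alongside — exact enumeration when
both groups have ≤ 20 untied observations, normal approximation otherwise.

## Panel design

Four strategies, differing in what seeds a module:

* **Cell-centric** — genes with Pearson r > 0.5 (log view) to any of a
  target type's reference markers; a top-15 fallback when fewer qualify;
  genes claimed by several targets are removed everywhere, while
  reference markers always stay in their own module exactly once.
* **Feature-gene** — candidate genes having ≥ 5 partners at r > 0.7 form
  a correlation graph (edges kept at r ≥ 0.6) partitioned by Leiden
  (modularity objective, resolution 1.0, fixed seed); partitions are
  sub-clustered by average-linkage hierarchical clustering on 1 − r
  distance, cut into k parts by module size (> 30 genes → 6, 11–30 → 4,
  6–10 → 2, < 6 → 1), dropping single-gene subclusters. The correlation
  substrate is a flag: the global-mean binarized matrix (as used for one
  published cortex panel) or the log view (generic default; the binarized
  substrate loses correlation on references with moderate library sizes).
* **NMF-program** — consumes an external non-negative gene × program
  loading matrix (the factorization itself is out of scope): top 50 genes
  per program, minus blocklisted names, minus genes whose maximum signed
  correlation to another program's genes exceeds 0.3 or whose maximum
  within-program correlation falls below 0.02.
* **Hybrid DE-seeded** — per cluster, DE genes (≤ 50, log-FC ≥ 0.25) are
  pruned greedily: while any pairwise correlation is ≤ 0.1, remove the
  gene whose best correlation to the others is weakest. Each iteration
  removes exactly one gene, so termination is guaranteed; this
  interpretation of "remove the genes least correlated to the rest" makes
  monotone progress toward the floor. Modules under 5 genes are dropped,
  as are mitochondrial names.

Gene-name filters drop ids matching a blocklisted prefix (`Mt`, `Gm`,
`Rp`) immediately followed by digits; whether the digits must be
immediate is a flag (immediate by default — `Gm12345` is dropped,
`Gma1` kept). Probe counts k_i ≥ 1 attach per gene via a lookup table
with a default.

## Signal model and panel evaluation

Signals are computed on the cell-scaled view: gene signal = probes ×
cluster mean; module signal = sum over genes. Signal Gain divides by the
reference gene's signal (general — for cell-centric panels built around a
named marker) or the maximum member signal (conservative — for module
panels without one). The Signal Specificity Ratio divides the target
signal by the strongest off-target cluster signal (conservative) or the
off-target sum (general); larger is more specific, +inf when no
off-target signal exists. An SSR formula also circulates in inverted
orientation (off-target over target); this package uses target over
off-target throughout so that "higher is better" holds for both scores.

The meta-gene (module-cell) matrix sums cell-scaled counts of each
module's genes, unweighted by probes. Simulated re-clustering
standardizes modules, takes principal components, builds a kNN graph and
partitions it (Leiden or igraph multilevel Louvain, both seeded). The
ARI is computed from the contingency table with the standard permutation
model. The HVG baseline ranks genes by variance of trend-standardized
counts: a quadratic log₁₀ mean–variance trend with values clipped at
√n_cells. The trend fit assumes the mean spectrum is dominated by genes
without strong population structure, as in real references.

## Image quantification

Module rounds register to the nuclear round by phase correlation with
100× local upsampling; the returned (dy, dx) is the displacement of the
moving image, so applying its negation aligns it. The shift policy either
applies each round's own shift or, for large mosaics, discards shifts
exceeding 50 px in either direction and applies the survivors' mean to
all rounds. Background rounds are subtracted after identical alignment;
illumination is corrected by subtracting a scalar percentile (default
60th) of off-mask pixels. All subtractions clamp at zero because camera
intensities cannot be negative. Percentiles interpolate linearly between
order statistics everywhere, so fixture values are exact.

Nucleus masks come from Otsu-thresholded, Gaussian-smoothed images via a
distance-transform watershed; labels under 3000 px are discarded. Cell
masks grow each nucleus by a Euclidean distance (5/10/15 px presets),
assigning contested pixels to the nearest nucleus. Per-cell intensities
are means over mask pixels after alignment; pixels shifted out of bounds
are excluded from the mean rather than zero-filled to avoid edge bias.
Cells are QC-flagged (never silently dropped) by total intensity below a
percentile (15th/20th presets) or by a band rule: below a low per-module
percentile in every module or above a high percentile in more than 30
modules. The band percentiles are computed per module; whether the
published rule meant per-module or global distributions is ambiguous, so
the choice is parameterized. Parameter bundles for the four study designs
ship as presets `fig2`/`fig3`/`fig4`/`fig5`.

## Spatial statistics

Clustering of cell-by-module intensities mirrors the meta-gene pipeline
(z-scale → PCs → kNN → community detection), with optional per-cell
total normalization and log1p — the conventional single-cell
normalization, useful because overall per-cell brightness (RNA content,
program activity, optics) is a nuisance variable. Max-channel assignment
takes the argmax of per-channel normalized intensities, leaving cells
below 0.5 unassigned; ties go to the first channel with a warning.

Manders coefficients binarize each channel at a threshold (per-channel
Otsu by default — deterministic and parameter-free — and overridable) and
report the fraction of each channel's supra-threshold pixels that are
supra-threshold in the other; the denominator of M2 is the C2 > t2 count
(the symmetric definition). Per-cell gain is the ratio of module-panel to
single-gene FISH mean intensity under identical masks, with zero-baseline
cells excluded and per-channel medians reported.

Cortical depth uses two equal-radius circles (default R = 25 500 px,
centers 10 000 px apart): depth = (R − distance to the outer center) / d,
so 0 at the pial arc, 1 at the inner arc along the center axis, computed
radially to the outer circle. Cells outside [0, 1] are flagged. The depth
density is an explicit fixed-bandwidth Gaussian mixture (default 0.05),
not a variance-scaled KDE, so closed-form checks are exact.

Proximity analysis counts query cells within a closed ball (≤ radius,
default 100 μm) of each reference cell and compares the two count vectors
by a two-sided Mann–Whitney U test — exact enumeration for untied groups
of ≤ 20, normal approximation with tie correction otherwise, without
continuity correction so that the null case gives p = 1 symmetrically.
The fold change of medians is reported as group B over group A.

## Synthetic data: what it emulates, and what it does not

`simulate_reference` draws negative-binomial counts (variance
μ + μ²/θ; θ = ∞ is the Poisson limit) with three structural ingredients:

* a discrete cell-type effect — module genes' means multiply by
  `fold_change` (≥ 1) in the module's target type;
* a shared program activity — per module and cell, a lognormal factor
  (mean 1, `activity_sd`) multiplies all member genes, so module genes
  covary continuously as real co-regulated genes do, not only through the
  type indicator;
* a per-gene baseline-mean spectrum — background genes draw lognormal
  means (`gene_mean_sd`) around `baseline_mean`, planted module genes sit
  exactly at `baseline_mean` off-target.

Defaults: `baseline_mean` 2, `dispersion` 10, `activity_sd` 0.7,
`gene_mean_sd` 1.0. The activity SD is the load-bearing choice: the
discrete type effect alone cannot push within-module log-view correlation
past ≈ 0.43 at an off-state mean of 2 (zero-inflation flicker of the log
transform dominates), while a large shared activity (SD ≳ 1) makes
off-target module brightness overlap on-target brightness and caps
cell-type identifiability near 73 % even on noiseless ground truth.
SD 0.7 with a realistically sized library (a few thousand genes, ~10⁴
counts per cell, where the scaled-count unit is small and the log
flicker shrinks) satisfies both: ≥ 90 % of planted pairs exceed r = 0.7
at fold 8, and planted types remain separable. Benchmarks that measure
type recovery from images use fold 16 — a strong-effect regime — because
at fold 8 the shared activity still produces a few percent of off-target
cells brighter than their own module, which is a property of the
simulated biology, not of the pipeline.

Cells sit on a jittered hexagonal grid (spacing 18 px, jitter 2 px), so
disk non-overlap is guaranteed by construction and violations raise a
layout error. The tissue renderer draws each cell as a uniform disk whose
module-round value is the cell's summed module expression, modulated by a
multiplicative illumination field (a smooth quadratic by default), plus
constant background and Gaussian camera noise; rounds are displaced by
known shifts in Fourier space (periodic boundary), which makes planted
shifts exactly recoverable by phase correlation. A configurable gene
subset is flagged mitochondrial so QC filters can be exercised.

Not emulated: optical point-spread functions, 3-D stacks, molecular
spots, cell-shape variation, segmentation errors (the ground-truth label
map is exact), spatial autocorrelation of cell types, batch or section
effects, and ambient RNA. Passing benchmarks therefore demonstrate the
correctness and composition of the algorithms under a faithful generative
model of signal and noise — not performance on real tissue, where
segmentation quality and optical artifacts dominate.

## Benchmark problem sizes

The packaged benchmarks use 3000 cells × 5000 genes × 10 replicates for
module recovery (the smallest library at which the log-view correlation
regime matches real references), 400 cells in a 400 × 400 px field for
the imaging round trip, and 500 cells per group with ~6000 query cells
for the proximity analysis. Formula oracles run on 20 random fixtures
(50 for Manders) with agreement required to 10⁻⁹ or better.

## Known limitations

* The NMF loading matrix is consumed, never computed; oligo sequence
  design is out of scope entirely.
* Watershed segmentation is a deliberate fallback; production use on real
  images would swap in a learned segmenter and feed the label map in.
* SG/SSR are point predictions; no uncertainty is attached.
* Leiden/Louvain determinism is per (igraph, leidenalg) version; seeds
  are fixed but partitions may differ across library versions.
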