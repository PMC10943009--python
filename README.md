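# modfish

Gene-module FISH panel design, evaluation and image analysis.

Multiplexed FISH assays usually image one gene per probe set. An
alternative is to hybridize probes against a whole *module* of co-expressed
genes at once, so that each cell type (or gene-expression program) lights
up as one bright channel. That buys a large sensitivity gain — the signal
is the sum over all member genes — at the risk of crosstalk when module
genes are also expressed in other cell types. `modfish` provides the
computational side of such an assay:

* **Panel design** from a scRNA-seq reference, by four strategies:
  cell-centric marker correlation, feature-gene correlation-graph modules
  (Leiden partitioning with hierarchical sub-clustering), modules from an
  external NMF gene-program loading matrix, and hybrid DE-seeded modules
  pruned to a pairwise-correlation floor.
* **Panel evaluation** with the predicted signal model. For a module
  P = {g_1 … g_n} with probe counts k_i targeting cluster C:

  - signal(g_i, C) = k_i · mean cell-scaled expression of g_i in C
  - signal(P, C) = Σ_i signal(g_i, C)
  - **Signal Gain** SG = signal(P, C) / signal(g_ref, C) (general) or
    signal(P, C) / max_i signal(g_i, C) (conservative)
  - **Signal Specificity Ratio** SSR = signal(P, C) / max_{C′≠C}
    signal(P, C′) (conservative); SSR → 1 means the target is
    indistinguishable from its strongest off-target cluster.

  Plus module-level re-clustering of the reference ("meta-gene" matrix)
  scored by the Adjusted Rand Index, with a highly-variable-gene baseline.
* **Image quantification**: watershed nucleus segmentation, sub-pixel
  phase-correlation registration of module rounds to the nuclear stain,
  shift-acceptance policy, background and illumination correction, mask
  dilation, percentile normalization, per-cell mean intensities and QC.
* **Spatial statistics**: graph-based clustering of the cell-by-module
  matrix, max-channel assignment, Manders overlap (crosstalk), per-cell
  gain against a single-molecule FISH baseline, cortical-depth geometry
  and kernel densities, and neighborhood proximity tests (Mann-Whitney).
* **Synthetic data** throughout: a negative-binomial reference generator
  with planted cell types and co-expression modules, and a tissue-image
  renderer with known shifts, illumination and noise, so every stage can
  be validated against ground truth without downloads.

## Worked example

`examples/03_quantify_images.py` renders four module rounds with planted
shifts and 5 % camera noise, registers, quantifies and clusters:

```
round m0: planted shift (+0.0, +0.0), measured (-0.00, -0.00)
round m1: planted shift (+3.0, -2.0), measured (+3.00, -2.00)
round m2: planted shift (-4.0, +5.0), measured (-4.00, +5.00)
round m3: planted shift (+1.5, +2.5), measured (+1.50, +2.50)

300 cells x 4 modules; 45 cells flagged by the 15th-percentile total-intensity QC
clustering QC-passing cells: 4 clusters, ARI vs planted types = 0.967
```

Registration recovers every planted shift to two decimals; clustering the
per-cell module intensities re-identifies the planted cell types almost
perfectly (ARI 0.97; 1.0 would be exact). The other examples cover panel
design (`01`), SG/SSR scoring and meta-gene re-clustering (`02`) and
crosstalk/depth/proximity statistics (`04`); each prints a line explaining
its numbers.

A thin CLI mirrors the pipeline stages:

```bash
modfish simulate --config cfg.json --out sim/
modfish design --strategy hybrid --counts sim/matrix.mtx --labels sim/labels.csv --out panel.csv
modfish evaluate --counts sim/matrix.mtx --labels sim/labels.csv --panel panel.csv --out scores.csv
modfish quantify --images rounds.tif --masks nuclei.tif --preset fig3 --out q
modfish cluster --matrix q_matrix.csv --cells q_cells.csv --preset fig3 --out clusters.csv
modfish proximity --cells cells.csv --group-a CAF1 --group-b CAF2 --query immune --radius-um 100
```

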