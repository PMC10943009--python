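"""Score a panel: predicted signal, Signal Gain and Signal Specificity Ratio.

Builds a small labelled reference, designs a panel, assigns probe counts
and prints the per-module score table.  SG says how much brighter the
module is than its best single gene in the target cluster (the single-gene
FISH baseline); SSR says how much brighter the target cluster is than the
most confusable off-target cluster — SSR near 1 means the module cannot
distinguish them.
"""

import modfish as mf

modules = [
    mf.ModuleSpec(f"m{t}", tuple(range(6 * t, 6 * t + 6)), t, fold_change=8.0)
    for t in range(3)
]
config = mf.SimulationConfig(
    n_cells=1500, n_genes=600, n_cell_types=3, modules=modules, seed=1
)
ref, truth = mf.simulate_reference(config)
views = mf.normalize_views(ref)

panel = mf.GenePanel([
    mf.PanelModule(
        m.module_id,
        [str(ref.gene_ids[i]) for i in m.gene_indices],
        target_label=f"type{m.target_cell_type}",
    )
    for m in modules
])
panel = mf.assign_probe_counts(panel, default_k=24)  # 24 probes per gene

table = mf.score_panel(views, panel, sg_mode="conservative",
                       ssr_mode="conservative")
print(table.to_string(index=False))
print()
print("SG_conservative ~ module size means member genes contribute evenly;")
print("SSR_conservative > 4 marks a cleanly separable cell type.")

# the meta-gene matrix used to simulate what the assay would measure;
# log-transformed first, as for any single-cell count matrix
import numpy as np

mcm = mf.module_cell_matrix(views, panel)
labels = mf.simulate_clustering(np.log1p(mcm), n_pcs=3, n_neighbors=15,
                                resolution=0.3, seed=0)
ari = mf.adjusted_rand_index(labels, views.cell_labels)
print(f"\nre-clustering cells on {len(panel)} meta-genes: ARI vs reference "
      f"labels = {ari:.3f}")
print("residual confusion reflects per-cell program-activity variation, "
      "not module design")
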