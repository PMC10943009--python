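"""Panel evaluation: predicted signals, Signal Gain, Signal Specificity
Ratio, the module-cell (meta-gene) matrix, simulated re-clustering and ARI.

The signal model: for a module P = {g_1 .. g_n} with probe counts k_i
targeting cluster C,

* ``signal(g_i, C)`` = k_i x mean cell-scaled expression of g_i over C;
* ``signal(P, C)``   = sum_i signal(g_i, C);
* Signal Gain (general)       = signal(P, C) / signal(g_ref, C);
* Signal Gain (conservative)  = signal(P, C) / max_i signal(g_i, C);
* SSR (conservative) = signal(P, C) / max over off-target clusters C' of
  signal(P, C') — larger means more specific, 1 means the target is
  indistinguishable from its strongest off-target;
* SSR (general)      = signal(P, C) / sum over off-target clusters.

The general Signal Gain suits cell-centric panels built around a named
reference marker; the conservative forms suit module panels with no single
reference gene.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .design import GenePanel, PanelModule
from .reference import NormalizedViews, standardize_genes

__all__ = [
    "gene_signal",
    "panel_signal",
    "signal_gain",
    "signal_specificity_ratio",
    "score_panel",
    "module_cell_matrix",
    "simulate_clustering",
    "adjusted_rand_index",
    "hvg_baseline",
]


def _cluster_cells_mask(views: NormalizedViews, labels, cluster) -> np.ndarray:
    labels = views.cell_labels if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise ValueError("cluster labels required")
    mask = labels == cluster
    if not mask.any():
        raise ValueError(f"empty cluster: {cluster!r}")
    return mask


def gene_signal(
    views: NormalizedViews, gene: str, cluster, k: int = 1, labels=None
) -> float:
    """k x mean cell-scaled expression of one gene in one cluster."""
    mask = _cluster_cells_mask(views, labels, cluster)
    row = views.gene_index([gene])[0]
    return float(k) * float(views.cell_scaled[row, mask].mean())


def panel_signal(
    views: NormalizedViews, module: PanelModule, cluster, labels=None
) -> float:
    """Sum of probe-weighted gene signals of a module in one cluster."""
    return float(
        sum(
            gene_signal(views, g, cluster, k=module.probes(g), labels=labels)
            for g in module.genes
        )
    )


def signal_gain(
    views: NormalizedViews,
    module: PanelModule,
    cluster,
    mode: str = "conservative",
    labels=None,
) -> float:
    """Ratio of the module signal to a single-gene baseline in the target.

    ``general`` divides by the module's (first) reference gene's signal;
    ``conservative`` divides by the maximum single-gene signal.
    """
    total = panel_signal(views, module, cluster, labels=labels)
    if mode == "general":
        if not module.reference_genes:
            raise ValueError(f"module {module.module_id} has no reference gene")
        denom = gene_signal(
            views,
            module.reference_genes[0],
            cluster,
            k=module.probes(module.reference_genes[0]),
            labels=labels,
        )
    elif mode == "conservative":
        if not module.genes:
            raise ValueError("empty module")
        denom = max(
            gene_signal(views, g, cluster, k=module.probes(g), labels=labels)
            for g in module.genes
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ZeroDivisionError(
            f"signal gain undefined: zero baseline signal in {cluster!r}"
        )
    return total / denom


def signal_specificity_ratio(
    views: NormalizedViews,
    module: PanelModule,
    target,
    mode: str = "conservative",
    labels=None,
    exclude_clusters: tuple = (),
) -> tuple[float, object]:
    """(SSR, most likely off-target cluster) for one module.

    Conservative: target signal over the strongest off-target signal.
    General: target signal over the summed off-target signal.  Returns
    ``inf`` when every off-target signal is zero.
    """
    lab = views.cell_labels if labels is None else np.asarray(labels, dtype=object)
    if lab is None:
        raise ValueError("cluster labels required")
    clusters = [
        c for c in pd.unique(lab) if c != target and c not in set(exclude_clusters)
    ]
    if not clusters:
        raise ValueError("need at least 2 clusters for specificity")
    target_sig = panel_signal(views, module, target, labels=lab)
    off = {c: panel_signal(views, module, c, labels=lab) for c in clusters}
    worst = max(off, key=lambda c: off[c])
    denom = off[worst] if mode == "conservative" else sum(off.values())
    if mode not in ("conservative", "general"):
        raise ValueError(f"unknown mode {mode!r}")
    ssr = np.inf if denom == 0 else target_sig / denom
    return float(ssr), worst


def score_panel(
    views: NormalizedViews,
    panel: GenePanel,
    labels=None,
    sg_mode: str = "conservative",
    ssr_mode: str = "conservative",
) -> pd.DataFrame:
    """Per-module score table: target signal, SG and SSR with off-target."""
    lab = views.cell_labels if labels is None else np.asarray(labels, dtype=object)
    rows = []
    for m in panel.modules:
        target = m.target_label
        if target is None:
            raise ValueError(f"module {m.module_id} has no target label to score")
        sg = signal_gain(views, m, target, mode=sg_mode, labels=lab)
        ssr, off = signal_specificity_ratio(
            views, m, target, mode=ssr_mode, labels=lab
        )
        rows.append(
            {
                "module_id": m.module_id,
                "target": target,
                "signal": panel_signal(views, m, target, labels=lab),
                f"SG_{sg_mode}": sg,
                f"SSR_{ssr_mode}": ssr,
                "off_target": off,
            }
        )
    return pd.DataFrame(rows)


def module_cell_matrix(views: NormalizedViews, panel: GenePanel) -> pd.DataFrame:
    """Meta-gene matrix: modules x cells sums of cell-scaled counts."""
    missing = [g for g in panel.all_genes() if g not in set(views.gene_ids)]
    if missing:
        raise KeyError(f"panel genes absent from reference: {missing}")
    rows = {}
    for m in panel.modules:
        idx = views.gene_index(m.genes)
        rows[m.module_id] = views.cell_scaled[idx].sum(axis=0)
    return pd.DataFrame(rows, index=views.cell_ids).T


def _community_labels(
    features: np.ndarray,
    n_pcs: int,
    n_neighbors: int,
    resolution: float,
    seed: int,
    algorithm: str = "leiden",
) -> np.ndarray:
    """Shared pipeline: PCs -> kNN graph -> graph community detection."""
    n_cells, n_feat = features.shape
    if n_cells <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} cells, got {n_cells}")
    if n_pcs > n_feat:
        warnings.warn(f"n_pcs clipped from {n_pcs} to {n_feat}")
        n_pcs = n_feat
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(features)
    knn = kneighbors_graph(pcs, n_neighbors=n_neighbors, mode="connectivity")
    adj = knn.maximum(knn.T).tocoo()  # symmetrize
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = ig.Graph(n=n_cells, edges=edges)
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
        )
        return np.asarray(part.membership)
    if algorithm == "louvain":
        rng_state = ig.set_random_number_generator  # igraph RNG is global
        import random

        rs = random.Random(seed)
        ig.set_random_number_generator(rs)
        try:
            part = g.community_multilevel(resolution=resolution)
        finally:
            ig.set_random_number_generator(random)
        del rng_state
        return np.asarray(part.membership)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def simulate_clustering(
    matrix: pd.DataFrame,
    n_pcs: int = 10,
    n_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    algorithm: str = "leiden",
) -> np.ndarray:
    """Re-cluster cells using modules as meta-gene features.

    ``matrix`` is modules x cells.  Modules are standardized across cells,
    principal components computed, a k-nearest-neighbour graph built and
    partitioned by graph community detection at the given resolution.
    """
    feats = standardize_genes(np.asarray(matrix, dtype=float)).T  # cells x modules
    return _community_labels(
        feats, n_pcs, n_neighbors, resolution, seed, algorithm=algorithm
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model Adjusted Rand Index from the contingency table."""
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a.astype(str), return_inverse=True)
    _, bi = np.unique(b.astype(str), return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)
    n = len(a)
    sum_ij = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def hvg_baseline(
    views: NormalizedViews, n_hvg: int = 2000, counts: np.ndarray | None = None
) -> list[str]:
    """Top-N highly variable genes by variance-stabilized standardized variance.

    Emulates the standard vst selection: a quadratic mean-variance trend is
    fitted in log10 space, counts are standardized by the trend's expected
    standard deviation with clipping at sqrt(n_cells), and genes are ranked
    by the variance of the clipped values.  Constant genes rank last.
    """
    if n_hvg > len(views.gene_ids):
        raise ValueError("n_hvg exceeds gene count")
    x = views.cell_scaled if counts is None else np.asarray(counts, dtype=float)
    n = x.shape[1]
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    ok = (mu > 0) & (var > 0)
    coef = np.polyfit(np.log10(mu[ok]), np.log10(var[ok]), deg=2)
    sd_exp = np.sqrt(10 ** np.polyval(coef, np.log10(np.where(ok, mu, 1.0))))
    std_var = np.zeros(len(mu))
    clip = np.sqrt(n)
    for i in np.nonzero(ok)[0]:
        z = np.clip((x[i] - mu[i]) / sd_exp[i], -clip, clip)
        std_var[i] = z.var(ddof=1)
    order = sorted(
        range(len(mu)), key=lambda i: (-std_var[i], str(views.gene_ids[i]))
    )
    return [str(views.gene_ids[i]) for i in order[:n_hvg]]
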