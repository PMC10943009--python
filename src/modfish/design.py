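"""Gene-panel construction by four strategies.

A panel groups genes into modules that are imaged together in one
fluorescence round; each gene carries a probe count.  Strategies:

* **cell-centric** — per target cell type, genes correlated with user-given
  reference markers (r > 0.5 by default), with a top-15 fallback and
  cross-target deduplication.
* **feature-gene** — candidate genes with enough strongly correlated
  partners form a correlation graph; Leiden partitioning then hierarchical
  sub-clustering by a size-dependent cut rule yields the modules.
* **NMF-program** — consumes an external gene x program factor-loading
  matrix; top-loading genes per program, pruned by within/cross-program
  correlation bounds, then split by correlation clustering.
* **hybrid DE-seeded** — per cluster, DE genes pruned greedily until the
  minimum pairwise correlation of the survivors clears a floor.

Correlations for the cell-centric and hybrid strategies are computed on the
log view; the feature-gene strategy correlates the binarized matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .reference import (
    NormalizedViews,
    binarize_expression,
    find_de_genes,
    gene_name_filter,
    prevalence_filter,
)

__all__ = [
    "PanelModule",
    "GenePanel",
    "CorrelationGraph",
    "pearson_matrix",
    "correlation_graph",
    "cell_centric_panel",
    "feature_gene_candidates",
    "leiden_modules",
    "hierarchical_subcluster",
    "feature_gene_panel",
    "nmf_program_modules",
    "hybrid_de_modules",
    "assign_probe_counts",
]


@dataclass
class PanelModule:
    module_id: str
    genes: list[str]
    probes_per_gene: dict[str, int] = field(default_factory=dict)
    reference_genes: list[str] = field(default_factory=list)
    target_label: str | None = None
    strategy: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.module_id}: duplicate genes")
        for g, k in self.probes_per_gene.items():
            if int(k) < 1:
                raise ValueError(f"module {self.module_id}: probes for {g} must be >= 1")

    def probes(self, gene: str, default: int = 1) -> int:
        return int(self.probes_per_gene.get(gene, default))


@dataclass
class GenePanel:
    modules: list[PanelModule]

    @property
    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def all_genes(self) -> list[str]:
        return [g for m in self.modules for g in m.genes]

    def __len__(self) -> int:
        return len(self.modules)

    def get(self, module_id: str) -> PanelModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "module_id": m.module_id,
                "probes": m.probes(g),
                "is_reference": g in m.reference_genes,
                "target_label": m.target_label,
                "strategy": m.strategy,
            }
            for m in self.modules
            for g in m.genes
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenePanel":
        mods = []
        for mid, grp in df.groupby("module_id", sort=False):
            mods.append(
                PanelModule(
                    module_id=str(mid),
                    genes=list(grp["gene"]),
                    probes_per_gene={
                        r.gene: int(r.probes) for r in grp.itertuples()
                    }
                    if "probes" in grp
                    else {},
                    reference_genes=list(grp.loc[grp.get("is_reference", False) == True, "gene"])
                    if "is_reference" in grp
                    else [],
                    target_label=(
                        None
                        if "target_label" not in grp or pd.isna(grp["target_label"].iloc[0])
                        else str(grp["target_label"].iloc[0])
                    ),
                    strategy=str(grp["strategy"].iloc[0]) if "strategy" in grp else "",
                )
            )
        return cls(mods)


def _corr_to_vector(matrix: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson r of each row of a genes x cells matrix against one vector."""
    n = matrix.shape[1]
    mc = matrix - matrix.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = n * matrix.std(axis=1) * vec.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, mc @ vc / np.where(denom > 0, denom, 1.0), -np.inf)
    return r


def pearson_matrix(
    matrix: np.ndarray, gene_subset: np.ndarray | None = None
) -> np.ndarray:
    """Gene-gene Pearson correlation of a genes x cells matrix.

    Zero-variance genes get correlation 0 to everything (diagonal stays 1)
    with a warning.  Requires at least two cells.
    """
    matrix = np.asarray(matrix, dtype=float)
    if gene_subset is not None:
        matrix = matrix[np.asarray(gene_subset)]
    if matrix.shape[1] < 2:
        raise ValueError("correlation needs at least 2 cells")
    sd = matrix.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes set to r=0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix)
    corr = np.atleast_2d(corr)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


@dataclass
class CorrelationGraph:
    """Thresholded gene-gene correlation graph (igraph backed)."""

    gene_ids: np.ndarray
    graph: ig.Graph
    edge_threshold: float


def correlation_graph(
    corr: np.ndarray, gene_ids, edge_threshold: float = 0.6
) -> CorrelationGraph:
    """Build an undirected weighted graph keeping edges with r >= threshold."""
    corr = np.asarray(corr)
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    keep = corr[iu] >= edge_threshold
    edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = corr[iu][keep].tolist()
    return CorrelationGraph(
        gene_ids=np.asarray(gene_ids, dtype=object),
        graph=g,
        edge_threshold=edge_threshold,
    )


def cell_centric_panel(
    views: NormalizedViews,
    labels: np.ndarray | None = None,
    reference_markers: dict[str, list[str]] | None = None,
    corr_threshold: float = 0.5,
    fallback_top: int = 15,
) -> GenePanel:
    """One module per target cell type, seeded by reference marker genes.

    Genes whose log-view correlation to any of the target's reference
    markers exceeds ``corr_threshold`` join the module; if fewer than
    ``fallback_top`` qualify, the top ``fallback_top`` genes by correlation
    are taken instead.  Non-reference genes claimed by more than one target
    are removed from every module; reference markers always remain in their
    own module (and only there).
    """
    if not reference_markers:
        raise ValueError("reference_markers required: {target: [marker, ...]}")
    all_refs = {g for refs in reference_markers.values() for g in refs}
    views.gene_index(sorted(all_refs))  # raises naming absent markers

    log = views.log_view
    raw_members: dict[str, list[str]] = {}
    for target, refs in reference_markers.items():
        ridx = views.gene_index(refs)
        # r of every gene to each reference marker; take the best marker
        r = np.full(len(views.gene_ids), -np.inf)
        for i in ridx:
            r = np.maximum(r, _corr_to_vector(log, log[i]))
        r[ridx] = -np.inf  # markers handled separately
        qualify = np.nonzero(r > corr_threshold)[0]
        if len(qualify) < fallback_top:
            order = np.argsort(-r, kind="stable")[:fallback_top]
            qualify = order[np.isfinite(r[order])]
        ranked = sorted(qualify, key=lambda i: (-r[i], str(views.gene_ids[i])))
        raw_members[target] = [str(views.gene_ids[i]) for i in ranked]

    counts: dict[str, int] = {}
    for genes in raw_members.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    modules = []
    for target, refs in reference_markers.items():
        keep = [
            g
            for g in raw_members[target]
            if counts[g] == 1 and g not in all_refs
        ]
        modules.append(
            PanelModule(
                module_id=str(target),
                genes=list(refs) + keep,
                reference_genes=list(refs),
                target_label=str(target),
                strategy="cell_centric",
            )
        )
    return GenePanel(modules)


def feature_gene_candidates(
    corr: np.ndarray, min_corr: float = 0.7, min_partners: int = 5
) -> np.ndarray:
    """Boolean mask of genes with >= min_partners partners at r > min_corr."""
    corr = np.asarray(corr)
    off = corr.copy()
    np.fill_diagonal(off, -np.inf)
    return (off > min_corr).sum(axis=1) >= min_partners


def leiden_modules(
    graph: CorrelationGraph,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden partition of the thresholded correlation graph.

    Returns one integer community label per node (singletons allowed);
    deterministic for a fixed seed.
    """
    g = graph.graph
    if g.vcount() == 0:
        raise ValueError("empty correlation graph")
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"] if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


_SUBCLUSTER_RULE = ((30, 6), (10, 4), (5, 2), (0, 1))


def subcluster_k(n_genes: int) -> int:
    """Dendrogram cut count by module size: >30 -> 6, 11-30 -> 4, 6-10 -> 2, <6 -> 1."""
    for floor, k in _SUBCLUSTER_RULE:
        if n_genes > floor:
            return k
    return 1


def hierarchical_subcluster(
    module_genes: list[str],
    views: NormalizedViews,
    drop_singletons: bool = True,
) -> list[list[str]]:
    """Split a gene module by average-linkage clustering on 1 - r distance.

    The dendrogram is cut into ``subcluster_k(len(module_genes))`` parts;
    single-gene subclusters are removed afterwards.
    """
    k = subcluster_k(len(module_genes))
    if k == 1 or len(module_genes) < 2:
        subs = [list(module_genes)]
    else:
        idx = views.gene_index(module_genes)
        corr = pearson_matrix(views.log_view[idx])
        dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
        assign = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
        subs = [
            [g for g, a in zip(module_genes, assign) if a == c]
            for c in np.unique(assign)
        ]
    if drop_singletons:
        subs = [s for s in subs if len(s) > 1]
    return subs


def feature_gene_panel(
    views: NormalizedViews,
    min_corr: float = 0.7,
    min_partners: int = 5,
    edge_threshold: float = 0.6,
    resolution: float = 1.0,
    min_cells: int = 5,
    max_fraction: float = 0.8,
    name_prefixes: tuple[str, ...] = ("Mt", "Gm"),
    subcluster: bool = True,
    substrate: str = "binarized",
    seed: int = 0,
) -> GenePanel:
    """Full feature-gene strategy: binarize, filter, graph, Leiden, subcluster.

    ``substrate`` selects the matrix the gene-gene correlation is computed
    on: ``"binarized"`` (global-mean thresholded, as used for the published
    cortex panel) or ``"log"`` (log-normalized expression, the generic
    co-expression default).
    """
    binary, _ = binarize_expression(views)
    keep = prevalence_filter(binary, min_cells=min_cells, max_fraction=max_fraction)
    kept_ids = views.gene_ids[keep]
    named = set(gene_name_filter(kept_ids, drop_prefixes=name_prefixes))
    mask = np.array([g in named for g in views.gene_ids]) & keep
    ids = views.gene_ids[mask]
    if substrate == "binarized":
        corr = pearson_matrix(binary[mask].astype(float))
    elif substrate == "log":
        corr = pearson_matrix(views.log_view[mask])
    else:
        raise ValueError(f"unknown substrate {substrate!r}")
    cand = feature_gene_candidates(corr, min_corr=min_corr, min_partners=min_partners)
    if not cand.any():
        raise ValueError("no candidate genes passed the correlation filter")
    cg = correlation_graph(corr[np.ix_(cand, cand)], ids[cand], edge_threshold)
    labels = leiden_modules(cg, resolution=resolution, seed=seed)

    modules: list[PanelModule] = []
    for c in np.unique(labels):
        genes = [str(g) for g in cg.gene_ids[labels == c]]
        subs = hierarchical_subcluster(genes, views) if subcluster else [genes]
        for j, sub in enumerate(subs):
            if not sub:
                continue
            mid = f"M{c}" if len(subs) == 1 else f"M{c}.{j}"
            modules.append(PanelModule(module_id=mid, genes=sub, strategy="feature_gene"))
    return GenePanel(modules)


def nmf_program_modules(
    loadings: pd.DataFrame,
    views: NormalizedViews,
    top_n: int = 50,
    corr_low: float = 0.02,
    corr_high: float = 0.3,
    name_prefixes: tuple[str, ...] = ("Gm",),
    subcluster: bool = False,
) -> GenePanel:
    """Modules from an external gene x program factor-loading matrix.

    Per program: take the ``top_n`` genes by loading, drop blocklisted
    names, then drop genes whose maximum correlation to another program's
    genes exceeds ``corr_high`` or whose maximum within-program correlation
    falls below ``corr_low`` (signed r on the log view).
    """
    if (loadings.values < 0).any():
        raise ValueError("factor loadings must be non-negative")
    shared = [g for g in loadings.index if g in set(views.gene_ids)]
    loadings = loadings.loc[shared]

    selected: dict[str, list[str]] = {}
    for prog in loadings.columns:
        top = loadings[prog].sort_values(ascending=False, kind="stable").head(top_n)
        selected[str(prog)] = gene_name_filter(list(top.index), drop_prefixes=name_prefixes)

    all_genes = sorted({g for gs in selected.values() for g in gs})
    if not all_genes:
        raise ValueError("no genes selected from loadings")
    idx = views.gene_index(all_genes)
    corr = pd.DataFrame(
        pearson_matrix(views.log_view[idx]), index=all_genes, columns=all_genes
    )

    modules: list[PanelModule] = []
    for prog, genes in selected.items():
        others = [g for p, gs in selected.items() if p != prog for g in gs]
        kept = []
        for g in genes:
            within = [h for h in genes if h != g]
            cross = [h for h in others if h != g]
            max_cross = corr.loc[g, cross].max() if cross else -np.inf
            max_within = corr.loc[g, within].max() if within else np.inf
            if max_cross > corr_high:
                continue
            if max_within < corr_low:
                continue
            kept.append(g)
        if not kept:
            warnings.warn(f"program {prog}: no genes survived correlation pruning")
            continue
        if subcluster:
            for j, sub in enumerate(hierarchical_subcluster(kept, views)):
                modules.append(
                    PanelModule(
                        module_id=f"{prog}.{j}", genes=sub, strategy="nmf_program"
                    )
                )
        else:
            modules.append(
                PanelModule(module_id=str(prog), genes=kept, strategy="nmf_program")
            )
    return GenePanel(modules)


def _prune_to_min_corr(
    corr: pd.DataFrame, min_pairwise_corr: float
) -> list[str]:
    """Greedily drop the gene with the weakest best partner until the whole
    pairwise correlation matrix clears the floor.  Each iteration removes
    exactly one gene, so termination is guaranteed."""
    genes = list(corr.index)
    while len(genes) > 1:
        sub = corr.loc[genes, genes].values.copy()
        np.fill_diagonal(sub, np.nan)
        if np.nanmin(sub) > min_pairwise_corr:
            break
        weakest = int(np.argmin(np.nanmax(sub, axis=1)))
        genes.pop(weakest)
    return genes


def hybrid_de_modules(
    views: NormalizedViews,
    labels: np.ndarray | None = None,
    max_de: int = 50,
    min_log_fc: float = 0.25,
    min_pairwise_corr: float = 0.1,
    min_module_size: int = 5,
    mito_prefixes: tuple[str, ...] = ("mt", "MT", "Mt"),
) -> GenePanel:
    """DE-seeded modules pruned to a minimum pairwise correlation floor.

    Per cluster, one-vs-rest DE genes (ranked by log fold-change) seed a
    module; genes are then removed greedily until every remaining pair
    correlates above ``min_pairwise_corr`` on the log view.  Mitochondrial
    names are excluded and modules below ``min_module_size`` dropped.
    """
    de = find_de_genes(views, labels, max_genes=max_de, min_log_fc=min_log_fc)
    modules: list[PanelModule] = []
    for cluster, table in de.items():
        genes = [
            g for g in table["gene"]
            if not any(str(g).startswith(p) for p in mito_prefixes)
        ]
        if not genes:
            warnings.warn(f"cluster {cluster}: DE list empty, module omitted")
            continue
        idx = views.gene_index(genes)
        corr = pd.DataFrame(
            pearson_matrix(views.log_view[idx]), index=genes, columns=genes
        )
        kept = _prune_to_min_corr(corr, min_pairwise_corr)
        if len(kept) < min_module_size:
            continue
        modules.append(
            PanelModule(
                module_id=str(cluster),
                genes=kept,
                target_label=str(cluster),
                strategy="hybrid_de",
            )
        )
    return GenePanel(modules)


def assign_probe_counts(
    panel: GenePanel,
    probes_per_gene: dict[str, int] | None = None,
    default_k: int = 1,
) -> GenePanel:
    """Attach a probe count to every gene (table lookup, else default)."""
    if default_k < 1:
        raise ValueError("default_k must be >= 1")
    table = probes_per_gene or {}
    for g, k in table.items():
        if int(k) < 1:
            raise ValueError(f"probe count for {g} must be >= 1")
    new = [
        PanelModule(
            module_id=m.module_id,
            genes=list(m.genes),
            probes_per_gene={g: int(table.get(g, default_k)) for g in m.genes},
            reference_genes=list(m.reference_genes),
            target_label=m.target_label,
            strategy=m.strategy,
        )
        for m in panel.modules
    ]
    return GenePanel(new)
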