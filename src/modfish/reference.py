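"""scRNA-seq reference preparation.

Quality control of a gene x cell count matrix and construction of the three
normalized views consumed by panel design and evaluation:

* ``cell_scaled`` — counts scaled so every cell sums to a fixed depth
  (default 10 000); the substrate for predicted-signal calculations.
* ``log_view`` — natural log of ``cell_scaled`` plus a pseudo-count; the
  substrate for differential expression and gene-gene correlation.
* ``gene_scaled`` — ``log_view`` standardized per gene (mean 0, unit sample
  variance); the substrate for dimensionality reduction.

Also provides one-vs-rest DE marker discovery, gene-name blocklist filters
(mitochondrial / predicted / ribosomal prefixes), global-mean binarization
and prevalence filtering used by the gene-centric design strategies.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneExpressionReference",
    "NormalizedViews",
    "qc_filter",
    "normalize_views",
    "standardize_genes",
    "find_de_genes",
    "gene_name_filter",
    "binarize_expression",
    "prevalence_filter",
]

_MITO_PREFIXES = ("mt-", "MT-", "Mt-")


@dataclass
class GeneExpressionReference:
    """Raw counts with gene/cell indices and optional cluster labels.

    counts is genes x cells, non-negative integers (dense ndarray).
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_labels: np.ndarray | None = None
    mito_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} count rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} count columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels, dtype=object)
            if len(self.cell_labels) != n_cells:
                raise ValueError("cell_labels length mismatch")
        if self.mito_flags is not None:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
            if len(self.mito_flags) != n_genes:
                raise ValueError("mito_flags length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def mito_mask(self) -> np.ndarray:
        """Per-gene mitochondrial mask; falls back to 'mt-'/'MT-' id prefixes."""
        if self.mito_flags is not None:
            return self.mito_flags
        return np.array(
            [str(g).startswith(_MITO_PREFIXES) for g in self.gene_ids], dtype=bool
        )

    def subset(self, gene_mask=None, cell_mask=None) -> "GeneExpressionReference":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return GeneExpressionReference(
            counts=self.counts[np.ix_(gm, cm)],
            gene_ids=self.gene_ids[gm],
            cell_ids=self.cell_ids[cm],
            cell_labels=None if self.cell_labels is None else self.cell_labels[cm],
            mito_flags=None if self.mito_flags is None else self.mito_flags[gm],
        )


@dataclass
class NormalizedViews:
    """The three matrix views, all genes x cells, sharing one index."""

    cell_scaled: np.ndarray
    log_view: np.ndarray
    gene_scaled: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 10_000.0
    pseudo_count: float = 1.0
    cell_labels: np.ndarray | None = field(default=None)

    def gene_index(self, genes) -> np.ndarray:
        """Integer row indices for gene ids; raises listing absentees."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from reference: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


def qc_filter(
    ref: GeneExpressionReference,
    min_genes_per_cell: int = 200,
    max_genes_per_cell: int = 3000,
    max_mito_fraction: float = 0.5,
    min_cells_per_gene: int = 10,
) -> GeneExpressionReference:
    """Remove low/high-complexity and high-mitochondrial cells, then rare genes.

    Cells are filtered first: a cell is kept when its number of unique
    expressed genes lies in [min_genes_per_cell, max_genes_per_cell] and its
    mitochondrial count fraction is <= max_mito_fraction.  Genes expressed in
    fewer than min_cells_per_gene of the surviving cells are then removed.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be non-negative")
    if min_genes_per_cell >= max_genes_per_cell:
        raise ValueError("min_genes_per_cell must be < max_genes_per_cell")

    expressed = ref.counts > 0
    genes_per_cell = expressed.sum(axis=0)
    totals = ref.counts.sum(axis=0).astype(float)
    mito = ref.mito_mask()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, ref.counts[mito].sum(axis=0) / np.maximum(totals, 1e-300), 0.0
        )

    band_ok = (genes_per_cell >= min_genes_per_cell) & (
        genes_per_cell <= max_genes_per_cell
    )
    mito_ok = mito_frac <= max_mito_fraction
    cell_keep = band_ok & mito_ok
    if not cell_keep.any():
        raise ValueError(
            "QC removed every cell "
            f"(gene-band removed {int((~band_ok).sum())}, "
            f"mito removed {int((~mito_ok).sum())})"
        )

    kept = ref.subset(cell_mask=cell_keep)
    cells_per_gene = (kept.counts > 0).sum(axis=1)
    gene_keep = cells_per_gene >= min_cells_per_gene
    return kept.subset(gene_mask=gene_keep)


def normalize_views(
    ref: GeneExpressionReference,
    scale_factor: float = 10_000.0,
    pseudo_count: float = 1.0,
) -> NormalizedViews:
    """Build the cell-scaled, log and gene-standardized views."""
    totals = ref.counts.sum(axis=0).astype(float)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"cells with zero total counts: {list(ref.cell_ids[zero[:5]])}"
        )
    cell_scaled = ref.counts / totals * scale_factor
    log_view = np.log(cell_scaled + pseudo_count)
    gene_scaled = standardize_genes(log_view)
    return NormalizedViews(
        cell_scaled=cell_scaled,
        log_view=log_view,
        gene_scaled=gene_scaled,
        gene_ids=ref.gene_ids.copy(),
        cell_ids=ref.cell_ids.copy(),
        scale_factor=scale_factor,
        pseudo_count=pseudo_count,
        cell_labels=None if ref.cell_labels is None else ref.cell_labels.copy(),
    )


def standardize_genes(matrix: np.ndarray) -> np.ndarray:
    """Standardize each row to mean 0, unit sample variance (ddof=1).

    Constant rows map to all zeros.
    """
    matrix = np.asarray(matrix, dtype=float)
    mu = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(matrix)
    ok = (sd > 0).ravel()
    out[ok] = (matrix[ok] - mu[ok]) / sd[ok]
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    # exact null enumeration where feasible, normal approximation otherwise
    if len(x) <= 20 and len(y) <= 20 and len(np.unique(np.r_[x, y])) == len(x) + len(y):
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        ).pvalue
    )


def find_de_genes(
    views: NormalizedViews,
    labels: np.ndarray | None = None,
    max_genes: int = 50,
    min_log_fc: float = 0.25,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest DE markers per cluster on the log view.

    Genes are ranked by log fold-change (difference of mean log expression,
    cluster vs rest); only genes at or above ``min_log_fc`` are kept,
    truncated at ``max_genes``.  A Wilcoxon rank-sum p-value is reported
    alongside but does not drive the ranking.  Ties in log fold-change break
    lexicographically by gene id.
    """
    labels = views.cell_labels if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise ValueError("cluster labels required")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"clusters with fewer than 2 cells: {list(small.index)}")

    out: dict[str, pd.DataFrame] = {}
    log = views.log_view
    for cl in uniq:
        in_cl = labels == cl
        lfc = log[:, in_cl].mean(axis=1) - log[:, ~in_cl].mean(axis=1)
        order = sorted(
            np.nonzero(lfc >= min_log_fc)[0],
            key=lambda i: (-lfc[i], str(views.gene_ids[i])),
        )[:max_genes]
        pvals = [_ranksum_p(log[i, in_cl], log[i, ~in_cl]) for i in order]
        out[cl] = pd.DataFrame(
            {
                "gene": views.gene_ids[order],
                "log_fc": lfc[order],
                "pvalue": pvals,
            }
        ).reset_index(drop=True)
    return out


def gene_name_filter(
    gene_ids,
    drop_prefixes: tuple[str, ...] = ("Mt", "Gm", "Rp"),
    immediate_digits: bool = True,
) -> list:
    """Drop ids whose name is a blocklisted prefix followed by digits.

    With ``immediate_digits`` (default) the digits must directly follow the
    prefix ("Gm12345" dropped, "Gma1" kept); otherwise digits anywhere after
    the prefix also match.  Case-sensitive.
    """
    if immediate_digits:
        pats = [re.compile("^" + re.escape(p) + r"\d") for p in drop_prefixes]
    else:
        pats = [re.compile("^" + re.escape(p) + r".*\d") for p in drop_prefixes]
    return [g for g in gene_ids if not any(p.match(str(g)) for p in pats)]


def binarize_expression(views: NormalizedViews) -> tuple[np.ndarray, float]:
    """Binarize the cell-scaled matrix at the global mean of all entries.

    Returns (binary matrix with entries in {0, 1}, threshold used); entries
    strictly above the mean become 1.
    """
    threshold = float(views.cell_scaled.mean())
    return (views.cell_scaled > threshold).astype(np.uint8), threshold


def prevalence_filter(
    matrix: np.ndarray,
    min_cells: int = 5,
    max_fraction: float = 0.8,
) -> np.ndarray:
    """Boolean gene mask keeping genes expressed in an interior band of cells.

    A gene is dropped when nonzero in fewer than ``min_cells`` cells or in
    more than ``max_fraction`` of all cells.
    """
    matrix = np.asarray(matrix)
    n_cells = matrix.shape[1]
    n_expr = (matrix != 0).sum(axis=1)
    return (n_expr >= min_cells) & (n_expr <= max_fraction * n_cells)
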