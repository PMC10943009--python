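"""Downstream analysis of cell-by-module intensity matrices.

Graph-based clustering of cells on meta-gene intensities, maximum-channel
cell-type assignment, Manders overlap (channel crosstalk), per-cell gain
against a single-gene FISH baseline, cortical-depth geometry and density,
and neighborhood proximity statistics with a Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .quantify import CellByModuleMatrix
from .score import _community_labels

__all__ = [
    "ClusteringResult",
    "MandersResult",
    "CorticalGeometry",
    "ProximityResult",
    "cluster_cells",
    "assign_max_channel",
    "manders_overlap",
    "per_cell_gain",
    "cortical_depth",
    "depth_density",
    "proximity_counts",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    cell_index: pd.Index
    resolution: float
    n_pcs: int
    n_neighbors: int
    seed: int
    algorithm: str
    embedding: np.ndarray | None = None


def cluster_cells(
    matrix: CellByModuleMatrix | pd.DataFrame,
    resolution: float = 0.8,
    n_pcs: int = 10,
    n_neighbors: int = 20,
    seed: int = 0,
    algorithm: str = "louvain",
    use_qc: bool = True,
    normalize_total: bool = False,
    log_transform: bool = False,
) -> ClusteringResult:
    """Cluster cells on z-scaled module intensities.

    Modules are standardized across cells, top principal components taken,
    a k-nearest-neighbour graph built and partitioned by Louvain or Leiden
    community detection.  QC-flagged cells are excluded when ``use_qc``.

    ``normalize_total`` first scales every cell's intensity vector to the
    median total, and ``log_transform`` applies log1p — the conventional
    single-cell normalization steps, useful when overall per-cell
    brightness is a nuisance variable.
    """
    if isinstance(matrix, CellByModuleMatrix):
        vals = matrix.passing() if use_qc else matrix.values
    else:
        vals = matrix
    arr = vals.to_numpy(dtype=float)
    if normalize_total:
        totals = arr.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("cells with non-positive total intensity")
        arr = arr / totals[:, None] * np.median(totals)
    if log_transform:
        arr = np.log1p(arr)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    z = (arr - mu) / np.where(sd > 0, sd, 1.0)
    labels = _community_labels(
        z, n_pcs, n_neighbors, resolution, seed, algorithm=algorithm
    )
    return ClusteringResult(
        labels=labels,
        cell_index=vals.index,
        resolution=resolution,
        n_pcs=n_pcs,
        n_neighbors=n_neighbors,
        seed=seed,
        algorithm=algorithm,
    )


def assign_max_channel(
    matrix: pd.DataFrame,
    min_normalized_intensity: float = 0.5,
    unassigned: str = "unassigned",
) -> pd.Series:
    """Per-cell label = brightest channel; dim cells stay unassigned.

    Expects per-channel normalized intensities.  Cells whose maximum falls
    below ``min_normalized_intensity`` are unassigned; exact ties go to the
    first channel in column order with a warning.
    """
    arr = matrix.to_numpy(dtype=float)
    best = arr.argmax(axis=1)  # first max wins on ties
    ties = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} cells tied across channels; first channel kept"
        )
    labels = matrix.columns.to_numpy(dtype=object)[best]
    labels[arr.max(axis=1) < min_normalized_intensity] = unassigned
    return pd.Series(labels, index=matrix.index, name="channel")


@dataclass
class MandersResult:
    M1: float
    M2: float
    t1: float
    t2: float
    channel1: str = "C1"
    channel2: str = "C2"


def manders_overlap(
    image1: np.ndarray,
    image2: np.ndarray,
    t1: float | None = None,
    t2: float | None = None,
    channel1: str = "C1",
    channel2: str = "C2",
) -> MandersResult:
    """Manders overlap coefficients between two intensity channels.

    M1 = |C1 > t1 and C2 > t2| / |C1 > t1| and M2 symmetrically with the
    C2 > t2 denominator.  Thresholds default to per-channel Otsu.  An empty
    denominator yields 0 with a warning.
    """
    a = np.asarray(image1, dtype=float)
    b = np.asarray(image2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    t1 = float(threshold_otsu(a)) if t1 is None else float(t1)
    t2 = float(threshold_otsu(b)) if t2 is None else float(t2)
    sup1 = a > t1
    sup2 = b > t2
    both = int((sup1 & sup2).sum())

    def frac(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: no supra-threshold pixels; coefficient set to 0")
            return 0.0
        return num / den

    return MandersResult(
        M1=frac(both, int(sup1.sum()), channel1),
        M2=frac(both, int(sup2.sum()), channel2),
        t1=t1,
        t2=t2,
        channel1=channel1,
        channel2=channel2,
    )


def per_cell_gain(
    module_matrix: pd.DataFrame,
    smfish_matrix: pd.DataFrame,
    min_cells: int = 1,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Per-cell ratio of module-panel to single-gene FISH intensity.

    Both matrices must cover the same cells (identical masks).  Cells with
    zero single-gene intensity are excluded per channel; returns the gain
    matrix (NaN where excluded), per-channel medians (NaN when fewer than
    ``min_cells`` valid cells), and the number of excluded entries.
    """
    if not module_matrix.index.equals(smfish_matrix.index):
        raise ValueError("matrices must cover identical cells")
    if list(module_matrix.columns) != list(smfish_matrix.columns):
        raise ValueError("matrices must share channel order")
    denom = smfish_matrix.to_numpy(dtype=float)
    num = module_matrix.to_numpy(dtype=float)
    valid = denom > 0
    n_excluded = int((~valid).sum())
    gains = np.where(valid, num / np.where(valid, denom, 1.0), np.nan)
    gains = pd.DataFrame(gains, index=module_matrix.index, columns=module_matrix.columns)
    if not valid.any():
        raise ValueError("no cells with positive single-gene signal")
    medians = pd.Series(
        {
            c: (gains[c].median() if gains[c].notna().sum() >= min_cells else np.nan)
            for c in gains.columns
        },
        name="median_gain",
    )
    return gains, medians, n_excluded


@dataclass
class CorticalGeometry:
    """Two equal-radius circles whose arcs bracket a cortical band.

    The outer circle approximates the pial surface; normalized depth is the
    radial distance inward from the outer arc divided by the distance
    between the two centers.
    """

    outer_center: tuple[float, float]  # (y, x) px
    inner_center: tuple[float, float]
    radius: float = 25_500.0

    def __post_init__(self) -> None:
        if self.center_distance <= 0:
            raise ValueError("circle centers must differ")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def center_distance(self) -> float:
        return float(np.hypot(
            self.outer_center[0] - self.inner_center[0],
            self.outer_center[1] - self.inner_center[1],
        ))


def cortical_depth(
    centroids: np.ndarray, geometry: CorticalGeometry
) -> pd.DataFrame:
    """Normalized depth per cell: (R - distance to outer center) / d.

    Depth 0 on the outer arc, rising inward to about 1 at the inner arc.
    Cells outside [0, 1] are flagged as outside the annulus, not dropped.
    """
    pts = np.asarray(centroids, dtype=float)
    dist = np.hypot(
        pts[:, 0] - geometry.outer_center[0], pts[:, 1] - geometry.outer_center[1]
    )
    depth = (geometry.radius - dist) / geometry.center_distance
    return pd.DataFrame(
        {"depth": depth, "inside_band": (depth >= 0) & (depth <= 1)}
    )


def depth_density(
    depths: np.ndarray,
    bandwidth: float = 0.05,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bandwidth Gaussian kernel density of normalized depths.

    Returns (grid, density); the density integrates to 1 over a support
    padded by 5 bandwidths beyond the data range.
    """
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise ValueError("no depths given")
    if grid is None:
        lo = min(d.min(), 0.0) - 5 * bandwidth
        hi = max(d.max(), 1.0) + 5 * bandwidth
        grid = np.linspace(lo, hi, 512)
    dens = stats.norm.pdf(grid[:, None], loc=d[None, :], scale=bandwidth).mean(axis=1)
    return grid, dens


@dataclass
class ProximityResult:
    counts_a: np.ndarray
    counts_b: np.ndarray
    median_a: float
    median_b: float
    quartiles_a: tuple[float, float]
    quartiles_b: tuple[float, float]
    fold_change: float  # median_b / median_a
    u_statistic: float
    p_value: float
    radius_um: float


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.r_[x, y]
    if np.ptp(pooled) == 0:  # every observation tied: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    exact = (
        len(x) <= 20 and len(y) <= 20
        and len(np.unique(pooled)) == len(pooled)
    )
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue)


def proximity_counts(
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    query_cells: np.ndarray,
    radius_um: float = 100.0,
    pixel_size: float = 1.0,
) -> ProximityResult:
    """Compare neighborhood query-cell counts around two reference groups.

    For every cell of groups A and B, count query cells within a closed
    ball of ``radius_um`` micrometres (coordinates in pixels, converted by
    ``pixel_size``).  The two count vectors are compared by a two-sided
    Mann-Whitney U test; the fold-change of medians is reported as B over A.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    a = np.asarray(cells_a, dtype=float)
    b = np.asarray(cells_b, dtype=float)
    q = np.asarray(query_cells, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty reference group")
    if q.size == 0:
        raise ValueError("empty query group")
    tree = cKDTree(q * pixel_size)
    r = radius_um
    counts_a = np.array(
        [len(tree.query_ball_point(p, r)) for p in a * pixel_size], dtype=int
    )
    counts_b = np.array(
        [len(tree.query_ball_point(p, r)) for p in b * pixel_size], dtype=int
    )
    u, p = _mannwhitney(counts_a, counts_b)
    med_a = float(np.median(counts_a))
    med_b = float(np.median(counts_b))
    fold = np.inf if med_a == 0 and med_b > 0 else (
        1.0 if med_a == med_b else med_b / med_a if med_a > 0 else np.nan
    )
    return ProximityResult(
        counts_a=counts_a,
        counts_b=counts_b,
        median_a=med_a,
        median_b=med_b,
        quartiles_a=(float(np.percentile(counts_a, 25)), float(np.percentile(counts_a, 75))),
        quartiles_b=(float(np.percentile(counts_b, 25)), float(np.percentile(counts_b, 75))),
        fold_change=float(fold),
        u_statistic=u,
        p_value=p,
        radius_um=radius_um,
    )
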