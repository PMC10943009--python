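"""Synthetic references and synthetic multi-round tissue images.

Every downstream stage of the pipeline (QC, panel design, scoring, image
quantification, spatial statistics) is testable against the planted ground
truth produced here, with no external downloads.

The expression model is negative binomial per gene and cell, parameterized
by (mean, dispersion) with variance ``mu + mu**2 / dispersion`` — the
standard overdispersed scRNA-seq noise model; ``dispersion = inf`` gives the
Poisson limit.  Planted gene modules multiply the mean of their member genes
by ``fold_change`` inside one target cell type and by a per-cell lognormal
program-activity factor shared across the module's genes; the combination
of the discrete type effect and the continuous shared activity induces the
strong within-module gene-gene correlation the design strategies look for.

The imaging model draws each cell as a disk at its ground-truth centroid.
In the round imaging module ``m``, the disk's pixel value is the cell's
summed expression over module ``m``'s genes, modulated by a multiplicative
illumination field, plus a constant background and Gaussian camera noise.
Each module round may be translated by a known (dy, dx) shift; shifting is
performed in Fourier space (periodic boundary), so planted shifts are
exactly recoverable by phase correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .reference import GeneExpressionReference

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "ImageStack",
    "SegmentationLabelMap",
    "simulate_reference",
    "simulate_tissue_images",
    "hex_grid_centroids",
    "polynomial_illumination",
]


@dataclass
class ModuleSpec:
    """A planted co-expressed gene module tied to one target cell type."""

    module_id: str
    gene_indices: tuple[int, ...]
    target_cell_type: int
    fold_change: float = 8.0


@dataclass
class SimulationConfig:
    n_cells: int = 3000
    n_genes: int = 100
    n_cell_types: int = 5
    modules: list[ModuleSpec] = field(default_factory=list)
    baseline_mean: float = 2.0
    gene_mean_sd: float = 1.0  # lognormal spread of per-gene baseline means
    dispersion: float = 10.0
    activity_sd: float = 0.7
    cell_type_proportions: tuple[float, ...] | None = None
    mito_gene_indices: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type_proportions is None:
            self.cell_type_proportions = tuple(
                np.full(self.n_cell_types, 1.0 / self.n_cell_types)
            )
        p = np.asarray(self.cell_type_proportions, dtype=float)
        if len(p) != self.n_cell_types:
            raise ValueError("one proportion per cell type required")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"cell_type_proportions sum to {p.sum()}, not 1")
        if np.any(p < 0):
            raise ValueError("negative cell type proportion")
        for m in self.modules:
            if len(m.gene_indices) == 0:
                raise ValueError(f"module {m.module_id} has no genes")
            if min(m.gene_indices) < 0 or max(m.gene_indices) >= self.n_genes:
                raise ValueError(f"module {m.module_id} gene index out of range")
            if m.fold_change < 1:
                raise ValueError(f"module {m.module_id} fold_change < 1")
            if not 0 <= m.target_cell_type < self.n_cell_types:
                raise ValueError(f"module {m.module_id} target type out of range")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.activity_sd < 0 or self.gene_mean_sd < 0:
            raise ValueError("activity_sd and gene_mean_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded at simulation time."""

    cell_type_labels: np.ndarray
    module_membership: dict[str, str]  # gene id -> module id
    module_ids: list[str]
    module_target_types: dict[str, int]
    cell_centroids: np.ndarray  # n_cells x 2, (y, x) pixels
    per_cell_module_signal: np.ndarray  # n_cells x n_modules
    gene_baseline_means: np.ndarray | None = None
    applied_shifts: dict[str, tuple[float, float]] | None = None


@dataclass
class ImageStack:
    """Named single-channel rounds of identical shape from one field of view."""

    rounds: dict[str, np.ndarray]
    pixel_size: float = 1.0  # micrometres per pixel
    fov_id: str = "fov0"
    nuclear_round: str = "nuclear"
    background_round: str | None = None

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.rounds.values()}
        if len(shapes) > 1:
            raise ValueError(f"rounds differ in shape: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def module_rounds(self) -> list[str]:
        skip = {self.nuclear_round, self.background_round}
        return [r for r in self.rounds if r not in skip]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.rounds.values())).shape


@dataclass
class SegmentationLabelMap:
    """Integer label image: 0 = background, positive labels = nuclei/cells."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    if np.isinf(dispersion):
        return rng.poisson(mu)
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[GeneExpressionReference, SyntheticTruth]:
    """Draw a synthetic scRNA-seq reference with planted modules.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    types = rng.choice(
        config.n_cell_types, size=config.n_cells, p=config.cell_type_proportions
    )

    # Per-module, per-cell lognormal activity shared by the module's genes:
    # co-expressed genes covary through their common program, not only
    # through the discrete cell-type indicator.  E[activity] = 1.
    # Background genes draw lognormal baseline means around baseline_mean
    # (E = baseline_mean), giving a realistic continuous mean spectrum;
    # planted module genes sit exactly at baseline_mean off-target, so the
    # stated fold_change is their true on/off contrast.
    gsd = config.gene_mean_sd
    gene_means = config.baseline_mean * (
        np.exp(rng.normal(-gsd**2 / 2, gsd, config.n_genes)) if gsd > 0
        else np.ones(config.n_genes)
    )
    planted = sorted({g for m in config.modules for g in m.gene_indices})
    gene_means[planted] = config.baseline_mean
    mu = np.repeat(gene_means[:, None], config.n_cells, axis=1)
    sd = config.activity_sd
    for m in config.modules:
        idx = np.asarray(m.gene_indices)
        activity = (
            np.exp(rng.normal(-sd**2 / 2, sd, config.n_cells)) if sd > 0 else 1.0
        )
        mu[idx] *= np.where(types == m.target_cell_type, m.fold_change, 1.0) * activity
    counts = _nb_counts(rng, mu, config.dispersion).astype(np.int64)

    gene_ids = np.array(
        [f"gene{i:04d}" for i in range(config.n_genes)], dtype=object
    )
    for i in config.mito_gene_indices:
        gene_ids[i] = f"mt-gene{i:04d}"
    cell_ids = np.array(
        [f"cell{i:05d}" for i in range(config.n_cells)], dtype=object
    )
    mito_flags = np.zeros(config.n_genes, bool)
    mito_flags[list(config.mito_gene_indices)] = True

    labels = np.array([f"type{t}" for t in types], dtype=object)
    ref = GeneExpressionReference(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_labels=labels,
        mito_flags=mito_flags,
    )

    module_ids = [m.module_id for m in config.modules]
    membership = {
        str(gene_ids[g]): m.module_id for m in config.modules for g in m.gene_indices
    }
    signal = np.stack(
        [counts[list(m.gene_indices)].sum(axis=0) for m in config.modules], axis=1
    ).astype(float) if config.modules else np.zeros((config.n_cells, 0))

    centroids = hex_grid_centroids(config.n_cells, rng=rng)
    truth = SyntheticTruth(
        cell_type_labels=labels,
        module_membership=membership,
        module_ids=module_ids,
        module_target_types={m.module_id: m.target_cell_type for m in config.modules},
        cell_centroids=centroids,
        per_cell_module_signal=signal,
        gene_baseline_means=gene_means,
    )
    return ref, truth


def hex_grid_centroids(
    n_cells: int,
    spacing: float = 18.0,
    jitter: float = 2.0,
    margin: float = 12.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(y, x) centroids on a jittered hexagonal grid — collision-free layout."""
    rng = np.random.default_rng(0) if rng is None else rng
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    pts = []
    row = 0
    while len(pts) < n_cells:
        y = margin + row * spacing * np.sqrt(3) / 2
        x_off = spacing / 2 if row % 2 else 0.0
        for c in range(n_cols):
            pts.append((y, margin + x_off + c * spacing))
            if len(pts) == n_cells:
                break
        row += 1
    pts = np.asarray(pts, dtype=float)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def polynomial_illumination(
    shape: tuple[int, int], strength: float = 0.2
) -> np.ndarray:
    """Smooth multiplicative 2-D quadratic field, brightest at the centre."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ny = (yy / max(shape[0] - 1, 1)) * 2 - 1
    nx = (xx / max(shape[1] - 1, 1)) * 2 - 1
    return 1.0 - strength * (ny**2 + nx**2) / 2


def _fourier_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    return np.real(
        np.fft.ifftn(ndi.fourier_shift(np.fft.fftn(image), shift))
    )


def _paint_disks(
    shape: tuple[int, int],
    centroids: np.ndarray,
    radius: float,
    values: np.ndarray,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = radius**2
    for (cy, cx), v in zip(centroids, values):
        y0, y1 = int(max(cy - radius - 1, 0)), int(min(cy + radius + 2, shape[0]))
        x0, x1 = int(max(cx - radius - 1, 0)), int(min(cx + radius + 2, shape[1]))
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r2
        img[y0:y1, x0:x1][sub] = v
    return img


def simulate_tissue_images(
    truth: SyntheticTruth,
    image_shape: tuple[int, int],
    signals: np.ndarray | None = None,
    module_ids: list[str] | None = None,
    cell_radius_px: float = 6.0,
    nuclear_level: float = 1000.0,
    background_level: float = 0.0,
    illumination_field: np.ndarray | None = None,
    noise_sd: float = 0.0,
    shifts: dict[str, tuple[float, float]] | None = None,
    include_background_round: bool = False,
    overlap_tolerance: float = 0.0,
    pixel_size: float = 1.0,
    seed: int = 0,
) -> tuple[ImageStack, SegmentationLabelMap]:
    """Render per-module rounds plus a nuclear round from planted truth.

    ``signals`` defaults to ``truth.per_cell_module_signal``.  The returned
    label map corresponds to the unshifted (nuclear) frame.  Raises a layout
    error when disks overlap beyond ``overlap_tolerance`` (fraction of disk
    pixels contested).
    """
    rng = np.random.default_rng(seed)
    signals = truth.per_cell_module_signal if signals is None else np.asarray(signals)
    module_ids = truth.module_ids if module_ids is None else module_ids
    if signals.shape[1] != len(module_ids):
        raise ValueError("one signal column per module round required")
    cents = truth.cell_centroids
    h, w = image_shape
    if (
        cents[:, 0].min() < cell_radius_px
        or cents[:, 1].min() < cell_radius_px
        or cents[:, 0].max() >= h - cell_radius_px
        or cents[:, 1].max() >= w - cell_radius_px
    ):
        raise ValueError("cells do not fit inside image_shape")

    # label map: paint labels and detect contested pixels
    labels = np.zeros(image_shape, dtype=np.int32)
    painted = np.zeros(image_shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = cell_radius_px**2
    contested = 0
    total = 0
    for i, (cy, cx) in enumerate(cents, start=1):
        y0, y1 = int(max(cy - cell_radius_px - 1, 0)), int(min(cy + cell_radius_px + 2, h))
        x0, x1 = int(max(cx - cell_radius_px - 1, 0)), int(min(cx + cell_radius_px + 2, w))
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r2
        region = labels[y0:y1, x0:x1]
        contested += int((painted[y0:y1, x0:x1][sub] > 0).sum())
        total += int(sub.sum())
        region[sub] = i
        painted[y0:y1, x0:x1][sub] += 1
    if total and contested / total > overlap_tolerance:
        raise ValueError(
            f"{contested} of {total} disk pixels overlap (> tolerance "
            f"{overlap_tolerance}); increase spacing or shrink cell_radius_px"
        )

    illum = (
        np.ones(image_shape) if illumination_field is None else illumination_field
    )
    if illum.shape != tuple(image_shape):
        raise ValueError("illumination field shape mismatch")
    shifts = {} if shifts is None else shifts

    rounds: dict[str, np.ndarray] = {}
    nuc = _paint_disks(image_shape, cents, cell_radius_px, np.full(len(cents), nuclear_level))
    rounds["nuclear"] = nuc + (
        rng.normal(0, noise_sd, image_shape) if noise_sd > 0 else 0.0
    )
    for m, mid in enumerate(module_ids):
        img = _paint_disks(image_shape, cents, cell_radius_px, signals[:, m])
        img = img * illum + background_level
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, image_shape)
        if mid in shifts and any(shifts[mid]):
            img = _fourier_shift(img, shifts[mid])
        rounds[mid] = np.clip(img, 0, None)

    background_round = None
    if include_background_round:
        background_round = "background"
        bg = np.full(image_shape, float(background_level))
        if noise_sd > 0:
            bg = bg + rng.normal(0, noise_sd, image_shape)
        rounds["background"] = np.clip(bg, 0, None)

    truth.applied_shifts = {mid: tuple(shifts.get(mid, (0.0, 0.0))) for mid in module_ids}
    stack = ImageStack(
        rounds=rounds,
        pixel_size=pixel_size,
        nuclear_round="nuclear",
        background_round=background_round,
    )
    return stack, SegmentationLabelMap(labels)
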