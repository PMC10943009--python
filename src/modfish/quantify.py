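"""From multi-round fluorescence images to a cell-by-module intensity matrix.

Pipeline: watershed nucleus segmentation on the nuclear stain, phase-
correlation registration of every module round to the nuclear round, a
shift-acceptance policy, background-round subtraction, scalar illumination
correction (percentile of off-mask pixels), nucleus-to-cell mask dilation,
per-image percentile normalization, per-mask mean intensities, and cell QC.

All percentile computations use linear interpolation between order
statistics.  Intensities are clamped at zero after any subtraction; pixels
carried out of bounds by alignment are excluded from per-cell means rather
than zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .simulate import ImageStack, SegmentationLabelMap

__all__ = [
    "CellByModuleMatrix",
    "segment_nuclei_watershed",
    "register_image",
    "shift_policy",
    "subtract_background",
    "illumination_correct",
    "dilate_masks",
    "normalize_image",
    "intensity_matrix",
    "qc_cells",
    "PRESETS",
]

# Named parameter bundles for the study designs this pipeline reproduces:
# a 5-channel cell-centric kidney panel, an 18-module and a 20-program
# cortex panel, and a 53-module large-FOV brain panel.
PRESETS: dict[str, dict] = {
    "fig2": dict(
        dilation_px=5, normalize_percentile=99, qc_mode=None,
        min_normalized_intensity=0.5,
    ),
    "fig3": dict(
        dilation_px=15, normalize_percentile=99,
        qc_mode="total_percentile", qc_percentile=15,
        resolution=0.8, n_pcs=10, n_neighbors=20,
    ),
    "fig4": dict(
        dilation_px=10, normalize_percentile=99,
        qc_mode="total_percentile", qc_percentile=20,
        resolution=1.2, n_pcs=10, n_neighbors=20,
    ),
    "fig5": dict(
        dilation_px=10, normalize_percentile=99,
        qc_mode="band", qc_low_percentile=0.2, qc_high_percentile=98,
        qc_max_high_modules=30, illumination_percentile=60,
        shift_mode="fov_average", max_abs_shift_px=50,
        resolution=0.6, n_pcs=20, n_neighbors=15,
    ),
}


@dataclass
class CellByModuleMatrix:
    """Cells x modules mean intensities plus per-cell metadata."""

    values: pd.DataFrame  # index = cell label, columns = module ids
    cells: pd.DataFrame  # centroid_y_px, centroid_x_px, centroid_y_um,
    #                      centroid_x_um, qc_flag, qc_reason
    pixel_size: float = 1.0
    fov_id: str = "fov0"

    def passing(self) -> pd.DataFrame:
        """Intensity rows of cells not flagged by QC."""
        return self.values.loc[~self.cells["qc_flag"]]


def segment_nuclei_watershed(
    nuclear_image: np.ndarray,
    smoothing_sigma: float = 2.0,
    threshold: float | None = None,
    min_area_px: int = 3000,
    min_distance: int = 10,
) -> SegmentationLabelMap:
    """Threshold + distance-transform watershed segmentation of nuclei.

    Foreground is an Otsu threshold of the smoothed image unless an explicit
    threshold is given; watershed seeds are local maxima of the distance
    transform.  Labels smaller than ``min_area_px`` are discarded and the
    rest relabelled contiguously.
    """
    img = np.asarray(nuclear_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    smooth = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if threshold is None:
        if smooth.max() == smooth.min():
            warnings.warn("blank nuclear image: no nuclei found")
            return SegmentationLabelMap(np.zeros(img.shape, np.int32))
        threshold = threshold_otsu(smooth)
    fg = smooth > threshold
    if not fg.any():
        warnings.warn("no foreground above threshold: no nuclei found")
        return SegmentationLabelMap(np.zeros(img.shape, np.int32))
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=fg)

    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area_px]
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return SegmentationLabelMap(out)


def register_image(
    moving: np.ndarray, fixed: np.ndarray, upsample_factor: int = 100
) -> tuple[float, float]:
    """Sub-pixel translation (dy, dx) of ``moving`` relative to ``fixed``.

    Estimated by phase correlation; applying the negated shift to ``moving``
    aligns it with ``fixed``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("images must share shape")
    if not moving.any() or not fixed.any():
        raise ValueError("cannot register an all-zero image")
    shift, _, _ = phase_cross_correlation(
        fixed, moving, upsample_factor=upsample_factor, normalization=None
    )
    # skimage returns the shift that registers `moving` onto `fixed`,
    # i.e. the negative of the displacement moving has undergone.
    return (-float(shift[0]), -float(shift[1]))


def shift_policy(
    shifts: dict[str, tuple[float, float]],
    max_abs_px: float = 50.0,
    mode: str = "per_image",
) -> dict[str, tuple[float, float]]:
    """Turn measured per-round shifts into the shifts actually applied.

    ``per_image`` applies each round's own shift.  ``fov_average`` discards
    shifts exceeding ``max_abs_px`` in either direction, then applies the
    mean of the survivors to every round.
    """
    if not shifts:
        raise ValueError("no shifts given")
    if mode == "per_image":
        return dict(shifts)
    if mode != "fov_average":
        raise ValueError(f"unknown mode {mode!r}")
    kept = [
        s for s in shifts.values()
        if abs(s[0]) <= max_abs_px and abs(s[1]) <= max_abs_px
    ]
    if not kept:
        raise ValueError(f"all shifts exceed {max_abs_px} px; cannot average")
    mean = tuple(np.mean(kept, axis=0))
    return {r: mean for r in shifts}


def subtract_background(
    image: np.ndarray, background_image: np.ndarray
) -> np.ndarray:
    """Pixel-wise background subtraction, clamped at zero."""
    image = np.asarray(image, dtype=float)
    background_image = np.asarray(background_image, dtype=float)
    if image.shape != background_image.shape:
        raise ValueError("background shape mismatch")
    return np.clip(image - background_image, 0.0, None)


def illumination_correct(
    image: np.ndarray, cell_masks: SegmentationLabelMap | np.ndarray,
    percentile: float = 60.0,
) -> np.ndarray:
    """Subtract the given percentile of off-mask pixel intensities.

    A scalar flat correction for slide-to-slide illumination offsets;
    clamped at zero.
    """
    labels = cell_masks.labels if isinstance(cell_masks, SegmentationLabelMap) else cell_masks
    image = np.asarray(image, dtype=float)
    if image.shape != labels.shape:
        raise ValueError("mask shape mismatch")
    off = image[labels == 0]
    if off.size == 0:
        raise ValueError("no pixels outside the cell masks")
    return np.clip(image - np.percentile(off, percentile), 0.0, None)


def dilate_masks(
    nuclei: SegmentationLabelMap, dilation_px: float = 15.0
) -> SegmentationLabelMap:
    """Grow every nucleus label by a Euclidean distance to form cell masks.

    Contested pixels go to the nearest nucleus; label identities are
    preserved.
    """
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    labels = nuclei.labels
    if dilation_px == 0 or not (labels > 0).any():
        return SegmentationLabelMap(labels.copy())
    dist, (iy, ix) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    out = labels.copy()
    grow = (labels == 0) & (dist <= dilation_px)
    out[grow] = labels[iy[grow], ix[grow]]
    return SegmentationLabelMap(out)


def normalize_image(image: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Divide by the given intensity percentile (values may exceed 1)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    denom = float(np.percentile(image, percentile))
    if denom == 0:
        raise ZeroDivisionError(f"{percentile}th percentile is zero")
    return image / denom


def _align(image: np.ndarray, applied_shift: tuple[float, float]) -> np.ndarray:
    """Undo a known (dy, dx) displacement; out-of-bounds pixels become NaN."""
    if applied_shift == (0.0, 0.0) or applied_shift == (0, 0):
        return np.asarray(image, dtype=float)
    return ndi.shift(
        np.asarray(image, dtype=float),
        (-applied_shift[0], -applied_shift[1]),
        order=1,
        mode="constant",
        cval=np.nan,
    )


def intensity_matrix(
    stack: ImageStack,
    cell_masks: SegmentationLabelMap,
    shifts: dict[str, tuple[float, float]] | None = None,
    subtract_background_round: bool = True,
    illumination_percentile: float | None = None,
    normalize_percentile: float | None = None,
    fov_id: str | None = None,
) -> CellByModuleMatrix:
    """Mean aligned, corrected intensity of every module round per cell mask.

    ``shifts`` maps module round -> (dy, dx) displacement relative to the
    nuclear round (e.g. from :func:`register_image` via
    :func:`shift_policy`); the negated shift is applied before averaging.
    Cells whose mask retains no valid pixels after alignment are flagged
    rather than dropped.
    """
    labels = cell_masks.labels
    if labels.shape != stack.shape:
        raise ValueError("masks and rounds must share shape")
    shifts = {} if shifts is None else shifts
    ids = cell_masks.ids
    bg = None
    if subtract_background_round and stack.background_round is not None:
        bg = stack.rounds[stack.background_round]

    cols = {}
    empty: set[int] = set()
    for rname in stack.module_rounds:
        img = _align(stack.rounds[rname], tuple(shifts.get(rname, (0.0, 0.0))))
        if bg is not None:
            img = np.where(np.isnan(img), img, np.clip(img - bg, 0.0, None))
        if illumination_percentile is not None:
            off = img[(labels == 0) & ~np.isnan(img)]
            if off.size == 0:
                raise ValueError("no off-mask pixels for illumination correction")
            img = np.clip(img - np.percentile(off, illumination_percentile), 0.0, None)
        if normalize_percentile is not None:
            denom = float(np.nanpercentile(img, normalize_percentile))
            if denom == 0:
                raise ZeroDivisionError("normalization percentile is zero")
            img = img / denom
        means = np.empty(len(ids))
        for j, lab in enumerate(ids):
            px = img[labels == lab]
            px = px[~np.isnan(px)]
            if px.size == 0:
                means[j] = 0.0
                empty.add(int(lab))
            else:
                means[j] = px.mean()
        cols[rname] = means

    cy, cx = np.array(ndi.center_of_mass(labels > 0, labels, ids)).T if len(ids) else (
        np.array([]), np.array([])
    )
    cells = pd.DataFrame(
        {
            "centroid_y_px": cy,
            "centroid_x_px": cx,
            "centroid_y_um": cy * stack.pixel_size,
            "centroid_x_um": cx * stack.pixel_size,
            "qc_flag": [int(l) in empty for l in ids],
            "qc_reason": ["no_valid_pixels" if int(l) in empty else "" for l in ids],
        },
        index=pd.Index(ids, name="cell"),
    )
    values = pd.DataFrame(cols, index=cells.index)
    return CellByModuleMatrix(
        values=values,
        cells=cells,
        pixel_size=stack.pixel_size,
        fov_id=fov_id or stack.fov_id,
    )


def qc_cells(
    matrix: CellByModuleMatrix,
    mode: str = "total_percentile",
    percentile: float = 15.0,
    low_percentile: float = 0.2,
    high_percentile: float = 98.0,
    max_high_modules: int = 30,
) -> CellByModuleMatrix:
    """Flag low-quality cells in place of dropping them.

    ``total_percentile``: flag cells whose summed intensity falls below the
    given percentile of all cell totals.  ``band``: flag cells below the
    low per-module percentile in every module, or above the high per-module
    percentile in more than ``max_high_modules`` modules.
    """
    vals = matrix.values
    if vals.empty:
        raise ValueError("empty intensity matrix")
    flags = matrix.cells["qc_flag"].to_numpy().copy()
    reasons = matrix.cells["qc_reason"].to_numpy(dtype=object).copy()

    if mode == "total_percentile":
        totals = vals.sum(axis=1).to_numpy()
        if np.ptp(totals) == 0:
            warnings.warn("all cell totals equal; no cells flagged")
        else:
            cut = np.percentile(totals, percentile)
            low = totals < cut
            reasons[low & ~flags] = f"total_below_p{percentile:g}"
            flags |= low
    elif mode == "band":
        arr = vals.to_numpy()
        if np.ptp(arr) == 0:
            warnings.warn("degenerate intensity matrix; no cells flagged")
        else:
            low_t = np.percentile(arr, low_percentile, axis=0)
            high_t = np.percentile(arr, high_percentile, axis=0)
            all_low = (arr < low_t).all(axis=1)
            many_high = (arr > high_t).sum(axis=1) > max_high_modules
            reasons[all_low & ~flags] = "low_in_all_modules"
            flags |= all_low
            reasons[many_high & ~flags] = f"high_in_over_{max_high_modules}_modules"
            flags |= many_high
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cells = matrix.cells.copy()
    cells["qc_flag"] = flags
    cells["qc_reason"] = reasons
    return CellByModuleMatrix(
        values=vals.copy(),
        cells=cells,
        pixel_size=matrix.pixel_size,
        fov_id=matrix.fov_id,
    )
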