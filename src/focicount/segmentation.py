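"""Nucleus segmentation from the DAPI channel.

The pipeline mirrors the classical ImageJ recipe for DAPI-stained nuclei:
global Huang fuzzy-entropy threshold, hole filling, Gaussian denoising
(default 3 sigma), a second Huang threshold on the denoised grayscale,
distance-transform watershed to split touching nuclei, then particle
analysis with a physical minimum-area filter (default 100 µm²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from .errors import DegenerateHistogramError
from .image_io import MultiChannelImage, pixel_area_um2

logger = logging.getLogger(__name__)

#: distance-map prominence below which neighbouring watershed seeds merge
WATERSHED_TOLERANCE = 2.0


@dataclass
class SegmentationParams:
    """Tunable parameters of nucleus detection.

    min_nucleus_area_um2 : smallest physical nucleus area kept (inclusive).
    gaussian_sigma : denoising blur scale in pixels.
    huang_bins : histogram bins used when thresholding wide (16-bit) data.
    exclude_border_nuclei : drop ROIs touching any image edge.
    """

    min_nucleus_area_um2: float = 100.0
    gaussian_sigma: float = 3.0
    huang_bins: int = 256
    exclude_border_nuclei: bool = False

    def __post_init__(self) -> None:
        if not self.min_nucleus_area_um2 > 0:
            raise ValueError("min_nucleus_area_um2 must be positive")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be non-negative")
        if self.huang_bins < 2:
            raise ValueError("huang_bins must be at least 2")


@dataclass(frozen=True)
class NucleusROI:
    """One segmented nucleus.

    ``mask`` is a full-image boolean array; masks of distinct ROIs within one
    image are disjoint. ``bbox`` is half-open ``(row_min, col_min, row_max,
    col_max)`` and tightly bounds the mask.
    """

    label: int
    mask: np.ndarray
    area_px: int
    area_um2: float
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]


def huang_threshold(histogram: np.ndarray) -> int:
    """Huang fuzzy-entropy threshold of an intensity histogram.

    For each candidate threshold ``t`` the pixels split into a low class
    (gray level <= t) and a high class (> t) with mean intensities m_lo, m_hi.
    Each gray level g gets a fuzzy membership µ = 1 / (1 + |g - m| / C) to its
    class, C being the intensity span of the histogram, and the candidate's
    fuzziness is the count-weighted Shannon entropy
    ``-sum h(g) [µ ln µ + (1-µ) ln(1-µ)]``. Returns the smallest ``t``
    minimising the fuzziness.

    Raises
    ------
    DegenerateHistogramError
        if fewer than two distinct gray levels have nonzero count.
    """
    h = np.asarray(histogram, dtype=np.float64)
    nz = np.flatnonzero(h)
    if nz.size < 2:
        raise DegenerateHistogramError(
            "histogram spans fewer than two distinct intensities"
        )
    gmin, gmax = int(nz[0]), int(nz[-1])
    C = float(gmax - gmin)
    g = np.arange(h.size, dtype=np.float64)
    cum_w = np.cumsum(h)
    cum_wg = np.cumsum(h * g)
    ts = np.arange(gmin, gmax)  # both classes nonempty on [gmin, gmax]
    m_lo = cum_wg[ts] / cum_w[ts]
    m_hi = (cum_wg[-1] - cum_wg[ts]) / (cum_w[-1] - cum_w[ts])
    # membership matrix: rows = candidates, cols = gray levels
    low = g[None, :] <= ts[:, None]
    m = np.where(low, m_lo[:, None], m_hi[:, None])
    mu = 1.0 / (1.0 + np.abs(g[None, :] - m) / C)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = mu * np.log(mu) + (1.0 - mu) * np.log1p(-mu)
    ent = np.where(mu >= 1.0, 0.0, ent)  # lim x->0 of x ln x
    fuzziness = -(h[None, :] * ent).sum(axis=1)
    return int(ts[np.argmin(fuzziness)])


def huang_threshold_grid(grid: np.ndarray, bins: int = 256) -> float:
    """Huang threshold of a 2-D intensity grid, on the grid's own scale.

    Narrow integer ranges are scanned exactly (one histogram bin per gray
    level); wider or non-integer data are binned to ``bins`` equal-width bins
    and the chosen bin's upper edge is mapped back to the intensity scale, so
    16-bit images stay tractable while 8-bit behaviour is exact.
    """
    flat = np.asarray(grid).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise DegenerateHistogramError("constant image")
    is_int = np.issubdtype(flat.dtype, np.integer)
    if is_int and hi - lo + 1 <= bins:
        hist = np.bincount((flat - int(lo)).astype(np.int64))
        t = huang_threshold(hist)
        return lo + t
    hist, edges = np.histogram(flat, bins=bins, range=(lo, hi))
    t = huang_threshold(hist)
    thr = edges[t + 1]
    if is_int:
        # all values falling in bins <= t must test as background under "> thr"
        thr = np.ceil(thr) - 1 if float(thr).is_integer() else np.floor(thr)
    return float(thr)


def binarize(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask, true where intensity exceeds the threshold."""
    return np.asarray(channel) > threshold


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the image border."""
    return ndi.binary_fill_holes(mask)


def gaussian_blur(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian filter with reflective boundary, clipped to the input range.

    ``sigma = 0`` is the identity. Returns float64.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if sigma == 0:
        return arr.copy()
    out = ndi.gaussian_filter(arr, sigma=sigma, mode="reflect")
    return np.clip(out, arr.min(), arr.max())


def watershed_split(mask: np.ndarray) -> np.ndarray:
    """Split touching objects by distance-transform watershed.

    Seeds are the h-maxima of the Euclidean distance transform (prominence
    tolerance :data:`WATERSHED_TOLERANCE`, so shallow double peaks inside one
    nucleus merge into a single seed). Flooding runs over the inverted
    distance map restricted to the foreground, leaving single-pixel watershed
    lines between labels. A foreground component whose maxima were all
    suppressed keeps one seed at its distance-map maximum.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    dist = ndi.distance_transform_edt(mask)
    # h-maxima transform: peaks separated by a saddle shallower than the
    # tolerance collapse onto one plateau, whose regional maximum is one seed
    rec = reconstruction(dist - WATERSHED_TOLERANCE, dist, method="dilation")
    seeds = local_maxima(rec, connectivity=2) & mask
    comps = cc_label(mask, connectivity=2)
    seeded = np.unique(comps[seeds])
    missing = np.setdiff1d(np.arange(1, comps.max() + 1), seeded)
    if missing.size:
        for pos in ndi.maximum_position(dist, comps, missing.tolist()):
            seeds[pos] = True
    markers = cc_label(seeds, connectivity=2)
    return watershed(-dist, markers=markers, mask=mask, watershed_line=True)


def _measure_rois(
    labels: np.ndarray, pixel_area: float, min_area_um2: float, exclude_border: bool
) -> list[NucleusROI]:
    """Particle analysis: area filter, then relabel 1..N in raster order."""
    nlab = int(labels.max())
    if nlab == 0:
        return []
    flat = labels.ravel()
    present, first_idx = np.unique(flat, return_index=True)
    order = [
        (idx, lab) for lab, idx in zip(present, first_idx) if lab > 0
    ]
    order.sort()
    rois: list[NucleusROI] = []
    h, w = labels.shape
    for _, old_label in order:
        mask = labels == old_label
        area_px = int(mask.sum())
        area_um2 = area_px * pixel_area
        if area_um2 < min_area_um2:
            continue
        rows, cols = np.nonzero(mask)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        if exclude_border and (
            bbox[0] == 0 or bbox[1] == 0 or bbox[2] == h or bbox[3] == w
        ):
            continue
        rois.append(
            NucleusROI(
                label=len(rois) + 1,
                mask=mask,
                area_px=area_px,
                area_um2=area_um2,
                bbox=bbox,
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    return rois


def detect_nuclei(
    image: MultiChannelImage, params: SegmentationParams | None = None
) -> list[NucleusROI]:
    """Segment nuclei from the nucleus-role channel.

    Steps: Huang threshold -> binary mask (the brighter class is foreground,
    matching DAPI-stained nuclei) -> fill holes -> Gaussian blur of the
    grayscale masked to the filled foreground -> second Huang threshold ->
    watershed split -> area filter at ``min_nucleus_area_um2`` (inclusive) ->
    relabel survivors 1..N in raster order of first pixel.

    A constant (all-background) nucleus channel yields an empty list with a
    logged warning rather than an error.
    """
    params = params or SegmentationParams()
    grid = image.nucleus_channel
    px_area = pixel_area_um2(image)
    try:
        mask = _huang_foreground(grid, params.huang_bins)
    except DegenerateHistogramError:
        logger.warning(
            "%s: constant nucleus channel; no nuclei detected", image.source_path
        )
        return []
    mask = fill_holes(mask)
    blurred = gaussian_blur(np.where(mask, grid, 0), params.gaussian_sigma)
    try:
        mask2 = _huang_foreground(blurred, params.huang_bins)
    except DegenerateHistogramError:
        logger.warning(
            "%s: degenerate denoised histogram; no nuclei detected",
            image.source_path,
        )
        return []
    labels = watershed_split(mask2)
    return _measure_rois(
        labels, px_area, params.min_nucleus_area_um2, params.exclude_border_nuclei
    )


def _huang_foreground(grid: np.ndarray, bins: int) -> np.ndarray:
    """Threshold and pick the brighter class as foreground."""
    thr = huang_threshold_grid(grid, bins=bins)
    mask = binarize(grid, thr)
    if mask.all() or not mask.any():
        return mask
    arr = np.asarray(grid, dtype=np.float64)
    if arr[mask].mean() < arr[~mask].mean():
        mask = ~mask
    return mask
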