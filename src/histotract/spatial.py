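"""Distance statistics for NSC clusters relative to tissue anatomy.

Covers: white-matter mask extraction from the myelin-stain channel,
cluster distances from the injection site with an exclusion radius,
cluster-weighted empirical cumulative distance distributions (with
weighted medians), the percentage of NSC signal resident in white
matter, and distances to the nearest white/grey matter interface pixel.

All physical distances are Euclidean in the 2-D section plane and are
reported in micrometres using the configured pixel scale (default
1.444 um/px, i.e. a 1000 px radius is 1444 um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

DEFAULT_PIXEL_SCALE_UM = 1.444
DEFAULT_EXCLUSION_RADIUS_PX = 1000.0

__all__ = [
    "TissueMasks",
    "CPDResult",
    "DEFAULT_PIXEL_SCALE_UM",
    "DEFAULT_EXCLUSION_RADIUS_PX",
    "interface_from_masks",
    "wm_mask_from_dii",
    "distances_from_injection",
    "weighted_cpd",
    "wm_fraction",
    "interface_distances",
]


@dataclass
class TissueMasks:
    """Mutually exclusive white-matter / grey-matter / background maps.

    ``interface_pixels`` is an (n, 2) array of (x, y) pixel coordinates
    on the WM/GM boundary; every interface pixel is 8-adjacent to both a
    WM and a GM pixel.
    """

    wm: np.ndarray
    gm: np.ndarray
    background: np.ndarray
    interface_pixels: np.ndarray
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm, dtype=bool)
        self.gm = np.asarray(self.gm, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if self.wm.shape != self.gm.shape or self.wm.shape != self.background.shape:
            raise ValueError("mask shapes differ")
        overlap = (self.wm & self.gm) | (self.wm & self.background) | (self.gm & self.background)
        if overlap.any():
            raise ValueError("wm/gm/background masks must be mutually exclusive")
        if not (self.wm | self.gm | self.background).all():
            raise ValueError("wm/gm/background masks must tile the image")
        self.interface_pixels = np.asarray(self.interface_pixels, dtype=np.int64).reshape(-1, 2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.wm.shape

    @property
    def brain(self) -> np.ndarray:
        return self.wm | self.gm

    def tissue_class_at(self, x: float, y: float) -> str:
        """'WM', 'GM' or 'background' at the pixel containing (x, y)."""
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < self.shape[0] and 0 <= ix < self.shape[1]):
            return "background"
        if self.wm[iy, ix]:
            return "WM"
        if self.gm[iy, ix]:
            return "GM"
        return "background"


@dataclass
class CPDResult:
    """Weighted empirical cumulative probability distribution.

    ``distances_um`` are sorted ascending; ``cum_prob`` is nondecreasing
    and ends at 1; ``median_um`` is the smallest value whose cumulative
    probability reaches 0.5.
    """

    distances_um: np.ndarray
    cum_prob: np.ndarray
    weights: np.ndarray
    median_um: float

    @property
    def n(self) -> int:
        return self.distances_um.size


_NEIGHBOR_FOOTPRINT = np.ones((3, 3), dtype=bool)  # 8-connectivity


def interface_from_masks(wm: np.ndarray, gm: np.ndarray) -> np.ndarray:
    """(x, y) coordinates of WM/GM boundary pixels.

    A pixel belongs to the interface when it is WM with a GM pixel in
    its 8-neighborhood, or GM with a WM neighbor.
    """
    wm = np.asarray(wm, dtype=bool)
    gm = np.asarray(gm, dtype=bool)
    near_gm = ndimage.binary_dilation(gm, structure=_NEIGHBOR_FOOTPRINT)
    near_wm = ndimage.binary_dilation(wm, structure=_NEIGHBOR_FOOTPRINT)
    boundary = (wm & near_gm) | (gm & near_wm)
    ys, xs = np.nonzero(boundary)
    return np.column_stack([xs, ys]).astype(np.int64)


def wm_mask_from_dii(
    dii_image: np.ndarray,
    threshold="otsu",
    min_component_px: int = 64,
    brain_mask: np.ndarray | None = None,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    smooth_sigma_px: float = 4.0,
) -> TissueMasks:
    """Segment white matter from the myelin-stain channel.

    The image is Gaussian-smoothed (``smooth_sigma_px``) before
    thresholding so that fiber texture (bright ridges / dark troughs
    within the tract) does not fragment the mask; WM = thresholded
    signal with components below ``min_component_px`` removed; GM = the
    brain mask minus WM.  ``brain_mask`` defaults to the full frame
    (phantoms have no off-section background).
    """
    img = np.asarray(dii_image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("dii image contains non-finite pixels")
    if smooth_sigma_px > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma_px, mode="reflect")
    if brain_mask is None:
        brain_mask = np.ones(img.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)

    if threshold == "otsu":
        thr = float(threshold_otsu(img[brain_mask]))
    else:
        thr = float(threshold)
    wm = (img > thr) & brain_mask
    if min_component_px > 1:
        labels, n = ndimage.label(wm, structure=_NEIGHBOR_FOOTPRINT)
        if n:
            sizes = ndimage.sum_labels(wm, labels, np.arange(1, n + 1))
            small = np.flatnonzero(sizes < min_component_px) + 1
            wm &= ~np.isin(labels, small)
    if not wm.any():
        raise ValueError(
            "no white matter found after thresholding; review the threshold "
            f"(used {thr:.4g}) and min_component_px"
        )
    gm = brain_mask & ~wm
    if not gm.any():
        warnings.warn("white matter fills the brain mask; no WM/GM interface", stacklevel=2)
    interface = interface_from_masks(wm, gm)
    return TissueMasks(
        wm=wm,
        gm=gm,
        background=~brain_mask,
        interface_pixels=interface,
        pixel_scale_um=pixel_scale_um,
    )


def distances_from_injection(
    centers: np.ndarray,
    injection_site: tuple[float, float],
    exclusion_radius_px: float = DEFAULT_EXCLUSION_RADIUS_PX,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    image_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean cluster-center distances from the injection site, in um.

    Returns ``(distances_um, excluded)`` where ``excluded`` flags
    clusters strictly inside the exclusion radius; those are omitted
    from downstream distributions.
    """
    if pixel_scale_um <= 0:
        raise ValueError("pixel_scale_um must be positive")
    x0, y0 = injection_site
    if image_shape is not None:
        h, w = image_shape
        if not (0 <= x0 < w and 0 <= y0 < h):
            raise ValueError("injection site lies outside the image")
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 2)
    d_px = np.hypot(centers[:, 0] - x0, centers[:, 1] - y0)
    excluded = d_px < exclusion_radius_px
    return d_px * pixel_scale_um, excluded


def weighted_cpd(values_um, weights=None) -> CPDResult:
    """Weighted empirical CDF of distances with its weighted median.

    The median is the smallest value at which cumulative weight reaches
    half the total.  Invariant to input ordering and to uniform weight
    rescaling.
    """
    values = np.asarray(values_um, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("weighted_cpd requires at least one value")
    if weights is None:
        w = np.ones_like(values)
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
    if w.size != values.size or np.any(w <= 0):
        raise ValueError("weights must be positive and match values in length")
    order = np.argsort(values, kind="stable")
    values, w = values[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    cum[-1] = 1.0
    median = float(values[np.searchsorted(cum, 0.5)])
    return CPDResult(distances_um=values, cum_prob=cum, weights=w, median_um=median)


def wm_fraction(centers: np.ndarray, weights, masks: TissueMasks) -> float:
    """Percentage of total cluster weight whose center lies in WM.

    Clusters whose center falls on background are counted in neither WM
    nor GM (a warning is emitted) but remain in the denominator so that
    WM% + GM% + unclassified% == 100.
    """
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 2)
    w = np.asarray(weights, dtype=np.float64).ravel()
    if w.size != centers.shape[0] or not np.any(w > 0):
        raise ValueError("weights must match centers and have positive total")
    classes = [masks.tissue_class_at(x, y) for x, y in centers]
    if any(c == "background" for c in classes):
        warnings.warn("cluster center(s) on background; counted as unclassified", stacklevel=2)
    wm_w = sum(wi for wi, c in zip(w, classes) if c == "WM")
    return 100.0 * wm_w / float(np.sum(w))


def interface_distances(
    centers: np.ndarray,
    masks: TissueMasks,
    pixel_scale_um: float | None = None,
) -> np.ndarray:
    """Distance (um) from each cluster center to the nearest interface pixel.

    Exact Euclidean nearest-neighbor search against the interface pixel
    set (equivalent to a distance transform sampled at the continuous
    center coordinates).
    """
    if masks.interface_pixels.shape[0] == 0:
        raise ValueError("interface pixel set is empty")
    if pixel_scale_um is None:
        pixel_scale_um = masks.pixel_scale_um
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 2)
    tree = cKDTree(masks.interface_pixels.astype(np.float64))
    d_px, _ = tree.query(centers)
    return np.asarray(d_px, dtype=np.float64) * pixel_scale_um
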