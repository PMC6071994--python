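"""NSC cluster detection, coalescing and tangent-orientation extraction.

Clusters are connected components of the NSC-stain channel above an
intensity threshold.  Cluster centers are merged into *coalesced
regions* by morphological dilation followed by erosion with Euclidean
disks (defaults 200 px / 100 px).  Regions that are too round
(circularity 4*pi*A/P^2 above a threshold, default 0.7) carry no
orientation information and are excluded; for the remaining regions a
second-degree polynomial is fitted in the region's principal frame and
the tangent of that curve nearest each member cluster center gives the
cluster orientation theta_NSC (degrees, axial on [0, 180)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from skimage.filters import threshold_otsu
from skimage.measure import approximate_polygon, find_contours

logger = logging.getLogger(__name__)

DEFAULT_DILATE_PX = 200
DEFAULT_ERODE_PX = 100
DEFAULT_CIRCULARITY_MAX = 0.7

_STRUCT8 = np.ones((3, 3), dtype=bool)

__all__ = [
    "NSCClusterSet",
    "CoalescedRegion",
    "detect_clusters",
    "coalesce",
    "region_circularity",
    "fit_region_polynomial",
    "cluster_tangent_angle",
    "assign_cluster_orientations",
    "DEFAULT_DILATE_PX",
    "DEFAULT_ERODE_PX",
    "DEFAULT_CIRCULARITY_MAX",
]


@dataclass
class NSCClusterSet:
    """Detected NSC clusters: centers, weights and bookkeeping.

    centers: (n, 2) float array of (x, y) pixel coordinates.
    sizes: per-cluster positive weight (pixel area by default).
    tissue_class: per-cluster 'WM' / 'GM' / 'background' / '' labels.
    region_id: coalesced-region label per cluster (-1 = none).
    theta_nsc: tangent orientation per cluster, NaN when unavailable.
    """

    centers: np.ndarray
    sizes: np.ndarray
    tissue_class: list[str] = field(default_factory=list)
    region_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    theta_nsc: np.ndarray = field(default=None)  # type: ignore[assignment]
    label_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 2)
        self.sizes = np.asarray(self.sizes, dtype=np.float64).ravel()
        n = len(self)
        if self.sizes.size != n:
            raise ValueError("sizes must match centers")
        if np.any(self.sizes <= 0):
            raise ValueError("cluster sizes must be positive")
        if not self.tissue_class:
            self.tissue_class = [""] * n
        if self.region_id is None:
            self.region_id = np.full(n, -1, dtype=np.int64)
        if self.theta_nsc is None:
            self.theta_nsc = np.full(n, np.nan)

    def __len__(self) -> int:
        return self.centers.shape[0]


@dataclass
class CoalescedRegion:
    """A merged cluster region with its polynomial fit.

    The fit is ``v = a u^2 + b u + c`` in the principal frame: image
    coordinates translated to the region centroid and rotated so the
    region's long (principal) axis lies along u.
    """

    label: int
    bbox: tuple[int, int, int, int]  # (ymin, xmin, ymax, xmax), half-open
    local_mask: np.ndarray
    circularity: float = np.nan
    excluded: bool = False
    principal_frame: tuple[float, float, float] | None = None  # (angle_deg, cx, cy)
    poly_coeffs: tuple[float, float, float] | None = None
    poly_degree: int = 2
    fit_u_range: tuple[float, float] | None = None
    member_clusters: list[int] = field(default_factory=list)
    theta_nsc_per_cluster: dict[int, float] = field(default_factory=dict)

    @property
    def area_px(self) -> int:
        return int(self.local_mask.sum())

    @property
    def pixel_coords(self) -> np.ndarray:
        """(n, 2) array of global (x, y) coordinates of region pixels."""
        ys, xs = np.nonzero(self.local_mask)
        return np.column_stack([xs + self.bbox[1], ys + self.bbox[0]]).astype(np.float64)

    def contains(self, x: float, y: float) -> bool:
        iy, ix = int(round(y)) - self.bbox[0], int(round(x)) - self.bbox[1]
        if 0 <= iy < self.local_mask.shape[0] and 0 <= ix < self.local_mask.shape[1]:
            return bool(self.local_mask[iy, ix])
        return False


def detect_clusters(
    nsc_image: np.ndarray,
    threshold="otsu",
    min_size_px: int = 5,
) -> NSCClusterSet:
    """Connected-component cluster detection on the NSC-stain channel.

    Components (8-connectivity) above the intensity threshold and of at
    least ``min_size_px`` pixels become clusters; the center is the
    intensity-weighted centroid and the size is the pixel area.  An
    image with no detections yields an empty set, not an error.
    """
    img = np.asarray(nsc_image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("nsc image contains non-finite pixels")
    if threshold == "otsu":
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    binary = img > thr
    labels, n_labels = ndimage.label(binary, structure=_STRUCT8)
    if n_labels == 0:
        logger.info("no clusters detected (threshold %.4g)", thr)
        return NSCClusterSet(centers=np.empty((0, 2)), sizes=np.empty(0), label_map=labels)

    idx = np.arange(1, n_labels + 1)
    areas = ndimage.sum_labels(binary, labels, idx)
    keep = areas >= min_size_px
    centers, sizes = [], []
    com = ndimage.center_of_mass(img, labels, idx[keep])  # intensity-weighted (y, x)
    for (cy, cx), area in zip(com, areas[keep]):
        centers.append((cx, cy))
        sizes.append(float(area))
    if not centers:
        logger.info("no clusters above min_size_px=%d", min_size_px)
        return NSCClusterSet(centers=np.empty((0, 2)), sizes=np.empty(0), label_map=labels)
    return NSCClusterSet(
        centers=np.asarray(centers), sizes=np.asarray(sizes), label_map=labels
    )


def _disk_dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean-disk dilation via the distance transform (fast for large radii)."""
    if radius_px <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_px


def _disk_erode(mask: np.ndarray, radius_px: float) -> np.ndarray:
    if radius_px <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    return dist > radius_px


def coalesce(
    clusters: NSCClusterSet,
    image_shape: tuple[int, int],
    dilate_px: float = DEFAULT_DILATE_PX,
    erode_px: float = DEFAULT_ERODE_PX,
    use_cluster_masks: bool = False,
    cluster_mask: np.ndarray | None = None,
) -> list[CoalescedRegion]:
    """Merge cluster centers into coalesced regions (dilate then erode).

    The binary map of cluster centers (or, with ``use_cluster_masks``,
    the full thresholded cluster mask) is dilated by a Euclidean disk of
    ``dilate_px`` and eroded by one of ``erode_px``; connected
    components of the result are the regions.  Each cluster is assigned
    to the region containing its center (nearest region pixel if the
    erosion removed the center itself).
    """
    if dilate_px <= erode_px:
        raise ValueError("dilate_px must exceed erode_px")
    if erode_px < 0:
        raise ValueError("erode_px must be >= 0")
    seed = np.zeros(image_shape, dtype=bool)
    if use_cluster_masks:
        if cluster_mask is None:
            if clusters.label_map is None:
                raise ValueError("use_cluster_masks requires a cluster_mask or label_map")
            cluster_mask = clusters.label_map > 0
        seed |= np.asarray(cluster_mask, dtype=bool)
    else:
        ys = np.clip(np.round(clusters.centers[:, 1]).astype(int), 0, image_shape[0] - 1)
        xs = np.clip(np.round(clusters.centers[:, 0]).astype(int), 0, image_shape[1] - 1)
        seed[ys, xs] = True

    merged = _disk_erode(_disk_dilate(seed, dilate_px), erode_px)
    labels, n_regions = ndimage.label(merged, structure=_STRUCT8)

    regions: list[CoalescedRegion] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in zip(range(1, n_regions + 1), slices):
        local = labels[sl] == lab
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        regions.append(CoalescedRegion(label=lab, bbox=bbox, local_mask=local))

    # cluster -> region assignment by center containment, nearest-label fallback
    if n_regions and len(clusters):
        ys = np.clip(np.round(clusters.centers[:, 1]).astype(int), 0, image_shape[0] - 1)
        xs = np.clip(np.round(clusters.centers[:, 0]).astype(int), 0, image_shape[1] - 1)
        lab_at = labels[ys, xs]
        missing = lab_at == 0
        if missing.any():
            _, (iy, ix) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
            lab_at = np.where(missing, labels[iy[ys, xs], ix[ys, xs]], lab_at)
        clusters.region_id = lab_at.astype(np.int64)
        for i, lab in enumerate(lab_at):
            regions[lab - 1].member_clusters.append(i)
    for region in regions:
        region.circularity = region_circularity(region)
    return regions


def region_circularity(region: CoalescedRegion) -> float:
    """Circularity 4*pi*area / perimeter^2 of a coalesced region.

    The perimeter is the total length of the sub-pixel iso-contours of
    the (zero-padded) region mask, so diagonal boundary steps contribute
    ~sqrt(2).  Contours are simplified (Douglas-Peucker, 0.8 px) to
    remove the half-pixel staircase that would otherwise overestimate
    curved perimeters; values may still slightly exceed 1 for small
    discretized disks.
    """
    if region.area_px == 0:
        raise ValueError("region is empty")
    padded = np.pad(region.local_mask.astype(np.float64), 1)
    perimeter = 0.0
    for contour in find_contours(padded, 0.5):
        simplified = approximate_polygon(contour, tolerance=0.8)
        perimeter += float(np.sum(np.hypot(*np.diff(simplified, axis=0).T)))
    if perimeter == 0:  # single isolated pixel
        return 1.0
    return 4.0 * np.pi * region.area_px / perimeter**2


def fit_region_polynomial(region: CoalescedRegion) -> CoalescedRegion:
    """Fit v = a u^2 + b u + c to region pixels in the principal frame.

    The principal frame rotates the pixel cloud about its centroid so
    the long axis (largest covariance eigenvector) lies along u; this
    keeps the function-graph fit well-posed for any region orientation.
    Rank-deficient configurations fall back to a degree-1 fit.
    """
    coords = region.pixel_coords
    if coords.shape[0] < 6:
        raise ValueError("region too small to fit (need >= 6 pixels)")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]  # unit vector (x, y)
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    ca, sa = np.cos(np.radians(angle)), np.sin(np.radians(angle))
    u = centered[:, 0] * ca + centered[:, 1] * sa
    v = -centered[:, 0] * sa + centered[:, 1] * ca

    degree = 2
    if np.ptp(u) < 3.0:
        degree = 1
    try:
        coeffs = np.polyfit(u, v, degree)
    except np.linalg.LinAlgError:
        degree = 1
        coeffs = np.polyfit(u, v, 1)
    if degree == 1:
        logger.warning("region %d: degenerate fit, fell back to degree 1", region.label)
        coeffs = np.concatenate([[0.0], coeffs])
    a, b, c = (float(x) for x in coeffs)
    region.principal_frame = (angle, float(centroid[0]), float(centroid[1]))
    region.poly_coeffs = (a, b, c)
    region.poly_degree = degree
    region.fit_u_range = (float(u.min()), float(u.max()))
    return region


def cluster_tangent_angle(
    region: CoalescedRegion, center: tuple[float, float]
) -> tuple[float, bool]:
    """theta_NSC: tangent angle (deg, [0,180)) of the region curve nearest a center.

    The nearest point on the fitted parabola is located by dense 1-px
    sampling over the fitted u-range extended by 10%, refined by bounded
    scalar minimization.  Returns ``(angle_deg, extrapolated)`` where
    ``extrapolated`` flags a nearest point outside the fitted u-range.
    """
    if region.poly_coeffs is None or region.principal_frame is None:
        raise ValueError("region has no polynomial fit")
    a, b, c = region.poly_coeffs
    angle, cx, cy = region.principal_frame
    ca, sa = np.cos(np.radians(angle)), np.sin(np.radians(angle))
    px, py = center[0] - cx, center[1] - cy
    pu = px * ca + py * sa
    pv = -px * sa + py * ca

    u_lo, u_hi = region.fit_u_range
    pad = 0.1 * max(u_hi - u_lo, 1.0)
    grid = np.arange(u_lo - pad, u_hi + pad + 1.0, 1.0)
    d2 = (grid - pu) ** 2 + (a * grid**2 + b * grid + c - pv) ** 2
    u0 = grid[int(np.argmin(d2))]
    res = minimize_scalar(
        lambda uu: (uu - pu) ** 2 + (a * uu**2 + b * uu + c - pv) ** 2,
        bounds=(u0 - 1.0, u0 + 1.0),
        method="bounded",
    )
    u_star = float(res.x)
    slope = 2.0 * a * u_star + b
    # tangent direction (1, slope) in the principal frame, rotated back
    tx = ca - slope * sa
    ty = sa + slope * ca
    theta = float(np.mod(np.degrees(np.arctan2(ty, tx)), 180.0))
    extrapolated = not (u_lo <= u_star <= u_hi)
    return theta, extrapolated


def assign_cluster_orientations(
    clusters: NSCClusterSet,
    regions: list[CoalescedRegion],
    circularity_max: float = DEFAULT_CIRCULARITY_MAX,
) -> NSCClusterSet:
    """Fit retained regions and fill per-cluster theta_NSC.

    Regions with circularity above ``circularity_max`` are flagged
    excluded and contribute no orientations (their clusters keep NaN).
    """
    for region in regions:
        if region.circularity > circularity_max:
            region.excluded = True
            continue
        if region.area_px < 6:
            region.excluded = True
            continue
        fit_region_polynomial(region)
        for i in region.member_clusters:
            theta, _ = cluster_tangent_angle(region, tuple(clusters.centers[i]))
            region.theta_nsc_per_cluster[i] = theta
            clusters.theta_nsc[i] = theta
    return clusters
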