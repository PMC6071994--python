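"""Histology-like phantoms with known orientation and distance structure.

Phantoms emulate a two-channel stained section: a myelin-like channel
carrying a curved, textured fiber tract (the white-matter band) over an
isotropic background, plus an NSC-stain-like channel into which
elongated cell clusters are planted with controllable alignment to the
tract.  Ground truth (centerline, tangent angles, cluster angles,
masks) is returned alongside, so every downstream stage can be
validated by round-trip.

All images are float64 in [0, 1]; the coordinate and angle conventions
match :mod:`histotract.tensor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .clusters import NSCClusterSet
from .spatial import DEFAULT_PIXEL_SCALE_UM, TissueMasks, interface_from_masks

__all__ = [
    "Phantom",
    "TractSpec",
    "make_stripe_image",
    "make_isotropic_crosshatch",
    "make_tract_phantom",
    "plant_clusters",
]


@dataclass
class TractSpec:
    """Parametric centerline for the white-matter band.

    kinds:
      line      -- segment from (x0, y0) to (x1, y1)
      parabola  -- y = y0 + curv * (x - cx)^2 for x in [x_min, x_max]
      arc       -- circle arc of given center/radius between two angles
                   (degrees, standard image convention)
    """

    kind: str = "line"
    params: dict = field(default_factory=dict)

    def sample(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (points (n,2) xy, tangent angles deg axial [0,180))."""
        t = np.linspace(0.0, 1.0, n)
        p = self.params
        if self.kind == "line":
            x0, y0, x1, y1 = p["x0"], p["y0"], p["x1"], p["y1"]
            xs = x0 + t * (x1 - x0)
            ys = y0 + t * (y1 - y0)
            ang = np.full(n, np.degrees(np.arctan2(y1 - y0, x1 - x0)))
        elif self.kind == "parabola":
            x_min, x_max = p["x_min"], p["x_max"]
            cx, y0, curv = p["cx"], p["y0"], p["curv"]
            xs = x_min + t * (x_max - x_min)
            ys = y0 + curv * (xs - cx) ** 2
            ang = np.degrees(np.arctan2(2.0 * curv * (xs - cx), 1.0))
        elif self.kind == "arc":
            cx, cy, r = p["cx"], p["cy"], p["radius"]
            a0, a1 = np.radians(p["angle0"]), np.radians(p["angle1"])
            phi = a0 + t * (a1 - a0)
            xs = cx + r * np.cos(phi)
            ys = cy + r * np.sin(phi)
            # tangent is perpendicular to the radius
            ang = np.degrees(phi + np.sign(a1 - a0) * np.pi / 2.0)
        else:
            raise ValueError(f"unknown tract kind: {self.kind!r}")
        return np.column_stack([xs, ys]), np.mod(ang, 180.0)


@dataclass
class Phantom:
    """Two-channel synthetic section with full ground truth."""

    dii_image: np.ndarray
    nsc_image: np.ndarray
    masks: TissueMasks
    tract_centerline: np.ndarray  # (n, 2) xy
    tract_tangent_deg: np.ndarray  # per centerline sample, axial [0, 180)
    truth_cluster_angles: np.ndarray  # per planted cluster, axial [0, 180)
    injection_site: tuple[float, float]
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dii_image.shape != self.nsc_image.shape:
            raise ValueError("dii and nsc channels must share a shape")
        angles = np.asarray(self.truth_cluster_angles, dtype=np.float64)
        if angles.size and (angles.min() < 0 or angles.max() >= 180):
            raise ValueError("truth angles must lie in [0, 180)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dii_image.shape


def _validate_size(size) -> tuple[int, int]:
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError("image size must be positive")
    return h, w


def make_stripe_image(
    size,
    period_px: float,
    angle_deg: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sinusoidal grating with stripes oriented at ``angle_deg``.

    Stripes run along the axial direction ``angle_deg`` (measured from
    the positive abscissa); intensity varies only across them.  Output
    is in [0, 1] before noise; deterministic for a fixed seed.
    """
    h, w = _validate_size(size)
    if period_px < 2:
        raise ValueError("period_px must be >= 2 (Nyquist)")
    if not 0 <= angle_deg < 180:
        raise ValueError("angle_deg must lie in [0, 180)")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    a = np.radians(angle_deg)
    # phase varies along the stripe normal (-sin a, cos a)
    phase = (-xx * np.sin(a) + yy * np.cos(a)) * (2.0 * np.pi / period_px)
    img = 0.5 + 0.5 * np.cos(phase)  # even in phase: axial sign drops out
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def make_isotropic_crosshatch(size, period_px: float) -> np.ndarray:
    """Sum of two equal-amplitude orthogonal sinusoids (isotropic texture).

    f(x, y) = sin(2 pi x / p) + sin(2 pi y / p), rescaled to [0, 1].
    Window-averaged gradient energy is equal along both axes, so the
    structure tensor smoothed over a full period is isotropic
    (coherence ~ 0).
    """
    h, w = _validate_size(size)
    if period_px < 2:
        raise ValueError("period_px must be >= 2 (Nyquist)")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    k = 2.0 * np.pi / period_px
    return (2.0 + np.sin(k * xx) + np.sin(k * yy)) / 4.0


def make_tract_phantom(
    size,
    tract: TractSpec,
    tract_halfwidth_px: float = 24.0,
    texture_period_px: float = 8.0,
    seed: int = 0,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    background_noise: float = 0.02,
) -> Phantom:
    """Curved textured white-matter band in an isotropic background.

    The band (WM mask) covers all pixels within ``tract_halfwidth_px``
    of the centerline and carries a sinusoidal ridge texture whose
    stripes run locally parallel to the centerline (phase = signed
    perpendicular distance).  Everything else is grey matter with faint
    smoothed noise.  The injection site sits on the centerline near its
    start.
    """
    h, w = _validate_size(size)
    n_samples = 8 * max(h, w)
    centerline, tangents = tract.sample(n_samples)
    margin = tract_halfwidth_px
    if (
        centerline[:, 0].min() < margin
        or centerline[:, 0].max() > w - 1 - margin
        or centerline[:, 1].min() < margin
        or centerline[:, 1].max() > h - 1 - margin
    ):
        raise ValueError("tract centerline exits image bounds (need halfwidth margin)")

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    tree = cKDTree(centerline)
    dist, idx = tree.query(pts, workers=-1)
    dist = dist.reshape(h, w)
    idx = idx.reshape(h, w)
    wm = dist <= tract_halfwidth_px

    # signed perpendicular offset from the centerline: cross(tangent, p - c)
    tan_rad = np.radians(tangents[idx])
    nearest = centerline[idx]
    dx = xx - nearest[..., 0]
    dy = yy - nearest[..., 1]
    signed = np.cos(tan_rad) * dy - np.sin(tan_rad) * dx

    rng = np.random.default_rng(seed)
    dii = np.empty((h, w))
    band_tex = 0.55 + 0.35 * np.sin(2.0 * np.pi * signed / texture_period_px)
    background = 0.12 + ndimage.gaussian_filter(
        rng.normal(0.0, background_noise, size=(h, w)), 1.5
    )
    dii[:] = np.where(wm, band_tex, background)
    dii = np.clip(dii, 0.0, 1.0)

    gm = ~wm
    masks = TissueMasks(
        wm=wm,
        gm=gm,
        background=np.zeros((h, w), dtype=bool),
        interface_pixels=interface_from_masks(wm, gm),
        pixel_scale_um=pixel_scale_um,
    )
    injection = tuple(float(v) for v in centerline[n_samples // 10])
    return Phantom(
        dii_image=dii,
        nsc_image=np.zeros((h, w)),
        masks=masks,
        tract_centerline=centerline,
        tract_tangent_deg=tangents,
        truth_cluster_angles=np.empty(0),
        injection_site=injection,  # type: ignore[arg-type]
        pixel_scale_um=pixel_scale_um,
        seed=seed,
    )


_BLOB_ASPECT = 4.0  # long/short sigma ratio of planted cluster blobs
_HALF_MAX_SCALE = np.sqrt(2.0 * np.log(2.0))  # sigma -> half-max semi-axis


def plant_clusters(
    phantom: Phantom,
    n_clusters: int,
    alignment: float,
    center_jitter_px: float,
    sizes,
    seed: int = 0,
    t_range: tuple[float, float] = (0.08, 0.92),
    max_retries: int = 100,
) -> NSCClusterSet:
    """Plant elongated cluster blobs along the tract into the NSC channel.

    Centers are spread along the centerline (arc positions in
    ``t_range``) with isotropic uniform jitter of ``center_jitter_px``.
    Each blob is an anisotropic Gaussian whose half-maximum ellipse has
    area ~ the requested size; its long-axis angle is

        tangent + (1 - alignment) * U(-90, 90)   (mod 180)

    so alignment=1 plants exactly along the tract and alignment=0 gives
    a uniform axial angle.  Truth angles are recorded on the phantom.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if not 0.0 <= alignment <= 1.0:
        raise ValueError("alignment must lie in [0, 1]")
    sizes = np.asarray(sizes, dtype=np.float64).ravel()
    if sizes.size != n_clusters or np.any(sizes <= 0):
        raise ValueError("sizes must be positive and of length n_clusters")

    rng = np.random.default_rng(seed)
    h, w = phantom.shape
    n_samples = phantom.tract_centerline.shape[0]
    t_positions = np.linspace(t_range[0], t_range[1], n_clusters)

    centers = np.empty((n_clusters, 2))
    angles = np.empty(n_clusters)
    classes: list[str] = []
    for i, t in enumerate(t_positions):
        j = int(round(t * (n_samples - 1)))
        base = phantom.tract_centerline[j]
        tangent = phantom.tract_tangent_deg[j]
        for attempt in range(max_retries + 1):
            jitter = rng.uniform(-center_jitter_px, center_jitter_px, size=2)
            cand = base + jitter
            ix, iy = int(round(cand[0])), int(round(cand[1]))
            if 0 <= ix < w and 0 <= iy < h and phantom.masks.brain[iy, ix]:
                break
        else:
            raise RuntimeError(
                f"cluster {i}: no in-brain placement found in {max_retries} retries"
            )
        centers[i] = cand
        angles[i] = np.mod(tangent + (1.0 - alignment) * rng.uniform(-90.0, 90.0), 180.0)
        classes.append(phantom.masks.tissue_class_at(*cand))

    _render_blobs(phantom.nsc_image, centers, angles, sizes)
    phantom.truth_cluster_angles = angles.copy()
    return NSCClusterSet(centers=centers, sizes=sizes.copy(), tissue_class=classes)


def _render_blobs(nsc_image: np.ndarray, centers, angles_deg, areas) -> None:
    """Draw anisotropic Gaussian blobs (max-composited) into the NSC channel."""
    h, w = nsc_image.shape
    for (cx, cy), ang, area in zip(centers, angles_deg, areas):
        sigma_s = np.sqrt(area / (np.pi * _BLOB_ASPECT * 2.0 * np.log(2.0)))
        sigma_l = _BLOB_ASPECT * sigma_s
        ext = int(np.ceil(4.0 * sigma_l))
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        ca, sa = np.cos(np.radians(ang)), np.sin(np.radians(ang))
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        blob = np.exp(-0.5 * ((u / sigma_l) ** 2 + (v / sigma_s) ** 2))
        np.maximum(nsc_image[y0:y1, x0:x1], blob, out=nsc_image[y0:y1, x0:x1])
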