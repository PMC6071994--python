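"""Cluster-weighted regression of NSC orientation on white-matter orientation.

For each cluster carrying a theta_NSC, the local white-matter
orientation theta_WM is the coherence-weighted mean axial orientation of
the structure-tensor field in a disk around the cluster center.  The
(theta_WM, theta_NSC) pairs are regressed by weighted least squares,
with the weight of every cluster equal to the total number of clusters
in its coalesced region.  Regressions are reported for all clusters and
for the WM-resident / GM-resident subsets.

Both angles are axial (theta and theta+180 identical).  Two wrap modes
are available: ``align`` shifts each theta_NSC by a multiple of 180 to
the representative nearest its theta_WM before fitting (the default);
``raw`` regresses the [0, 180) representatives as plotted.  The choice
can change the slope; see the module documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import CoalescedRegion, NSCClusterSet
from .spatial import TissueMasks
from .tensor import OrientationField, mean_axial_orientation

__all__ = [
    "RegressionResult",
    "local_wm_orientation",
    "axial_pair_alignment",
    "weighted_regression",
    "correlate_by_tissue",
]

DEFAULT_WM_RADIUS_PX = 25.0
DEFAULT_COHERENCE_MIN = 0.2


@dataclass
class RegressionResult:
    """Weighted least-squares fit of theta_NSC against theta_WM."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    weights_used: np.ndarray = field(default_factory=lambda: np.empty(0))
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    available: bool = True

    @classmethod
    def unavailable(cls) -> "RegressionResult":
        return cls(np.nan, np.nan, np.nan, 0, available=False)


def local_wm_orientation(
    fld: OrientationField,
    center: tuple[float, float],
    radius_px: float = DEFAULT_WM_RADIUS_PX,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
) -> float | None:
    """Coherence-weighted mean axial orientation around ``center``.

    Pixels within ``radius_px`` that are valid and have coherence >=
    ``coherence_min`` contribute with weight = coherence.  Returns None
    (point dropped from the regression) when no pixel qualifies.
    """
    h, w = fld.shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("center outside the field")
    x0, x1 = max(0, int(np.floor(cx - radius_px))), min(w, int(np.ceil(cx + radius_px)) + 1)
    y0, y1 = max(0, int(np.floor(cy - radius_px))), min(h, int(np.ceil(cy + radius_px)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    sel = inside & fld.valid[y0:y1, x0:x1] & (fld.coherence[y0:y1, x0:x1] >= coherence_min)
    if not sel.any():
        return None
    return mean_axial_orientation(
        fld.theta[y0:y1, x0:x1][sel], fld.coherence[y0:y1, x0:x1][sel]
    )


def axial_pair_alignment(theta_wm: float, theta_nsc: float) -> tuple[float, float]:
    """Shift theta_NSC by k*180 (k in {-1, 0, 1}) closest to theta_WM.

    Both inputs are axial representatives in [0, 180); the returned pair
    differs by at most 90 degrees in magnitude.
    """
    for t in (theta_wm, theta_nsc):
        if not 0 <= t < 180:
            raise ValueError("angles must lie in [0, 180)")
    candidates = theta_nsc + 180.0 * np.array([-1.0, 0.0, 1.0])
    best = candidates[np.argmin(np.abs(candidates - theta_wm))]
    return theta_wm, float(best)


def weighted_regression(pairs, weights) -> RegressionResult:
    """Weighted least squares of y on x with weighted r^2.

    r^2 = 1 - (weighted residual SS) / (weighted total SS about the
    weighted mean).  Invariant to uniform weight rescaling.
    """
    pairs = np.asarray(pairs, dtype=np.float64).reshape(-1, 2)
    w = np.asarray(weights, dtype=np.float64).ravel()
    if pairs.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if w.size != pairs.shape[0] or np.any(w <= 0):
        raise ValueError("weights must be positive and match pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all x identical; slope undefined")
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = np.sum(w * (y - slope * x - intercept) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 0.0 if ss_tot == 0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=int(pairs.shape[0]),
        weights_used=w,
        pairs=pairs,
    )


def build_orientation_pairs(
    clusters: NSCClusterSet,
    regions: list[CoalescedRegion],
    fld: OrientationField,
    wm_radius_px: float = DEFAULT_WM_RADIUS_PX,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
    wrap_mode: str = "align",
):
    """(theta_WM, theta_NSC) pairs with region-count weights and classes.

    A cluster contributes when it has a theta_NSC (its region was
    retained) and a defined local theta_WM.  The weight attached to each
    pair is the total cluster count of the cluster's coalesced region.
    """
    if wrap_mode not in ("align", "raw"):
        raise ValueError("wrap_mode must be 'align' or 'raw'")
    region_counts = {r.label: max(len(r.member_clusters), 1) for r in regions}
    pairs, weights, classes, indices = [], [], [], []
    for i in range(len(clusters)):
        t_nsc = clusters.theta_nsc[i]
        if not np.isfinite(t_nsc):
            continue
        t_wm = local_wm_orientation(
            fld, tuple(clusters.centers[i]), wm_radius_px, coherence_min
        )
        if t_wm is None:
            continue
        if wrap_mode == "align":
            t_wm, t_nsc = axial_pair_alignment(t_wm, float(t_nsc))
        pairs.append((t_wm, t_nsc))
        weights.append(float(region_counts.get(int(clusters.region_id[i]), 1)))
        classes.append(clusters.tissue_class[i])
        indices.append(i)
    return (
        np.asarray(pairs, dtype=np.float64).reshape(-1, 2),
        np.asarray(weights, dtype=np.float64),
        classes,
        indices,
    )


def correlate_by_tissue(
    clusters: NSCClusterSet,
    regions: list[CoalescedRegion],
    fld: OrientationField,
    masks: TissueMasks | None = None,
    wm_radius_px: float = DEFAULT_WM_RADIUS_PX,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
    wrap_mode: str = "align",
) -> dict[str, RegressionResult]:
    """Regressions over {all, WM-only, GM-only} cluster subsets.

    Subsets with fewer than two usable points (or no x spread) are
    marked unavailable rather than raising.
    """
    if masks is not None and not clusters.tissue_class[0:1]:
        pass  # classes already carried on the cluster set
    pairs, weights, classes, _ = build_orientation_pairs(
        clusters, regions, fld, wm_radius_px, coherence_min, wrap_mode
    )
    out: dict[str, RegressionResult] = {}
    for name, sel in (
        ("all", np.ones(len(classes), dtype=bool)),
        ("wm", np.array([c == "WM" for c in classes], dtype=bool)),
        ("gm", np.array([c == "GM" for c in classes], dtype=bool)),
    ):
        if sel.sum() < 2 or (sel.any() and np.ptp(pairs[sel, 0]) == 0):
            out[name] = RegressionResult.unavailable()
            continue
        out[name] = weighted_regression(pairs[sel], weights[sel])
    return out
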