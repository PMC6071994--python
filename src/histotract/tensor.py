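"""Structure-tensor orientation and coherence mapping.

Per-pixel 2x2 structure tensors are built from Gaussian-windowed outer
products of image gradients; their eigenstructure yields an orientation
angle (axial, degrees in [0, 180), measured from the positive abscissa)
and a coherence value in [0, 1]:

    C = (lambda_max - lambda_min) / (lambda_max + lambda_min)

C == 0 for locally isotropic texture, C == 1 for a single dominant
orientation.

Coordinate convention: arrays are indexed ``[y, x]`` with the origin at
the top-left corner and y increasing downward; angles are measured from
the +x axis toward +y.  Because orientation is axial (theta and
theta + 180 are the same fiber direction), this matches the
counter-clockwise mathematical convention up to a sign that cancels
modulo 180.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "OrientationField",
    "compute_gradients",
    "structure_tensor_field",
    "eigen_orientation",
    "coherence_of",
    "mean_axial_orientation",
    "orientation_field",
]

#: eigenvalue sums below this are treated as degenerate (flat) pixels
DEGENERATE_EPS = 1e-12


@dataclass
class OrientationField:
    """Per-pixel eigenstructure of the 2-D structure tensor.

    Attributes
    ----------
    lambda_max, lambda_min
        Largest / smallest eigenvalue fields (intensity^2 / px^2, >= 0).
    theta
        Orientation in degrees, axial on [0, 180), from the +x axis.
    coherence
        (lmax - lmin) / (lmax + lmin), in [0, 1]; 0 at degenerate pixels.
    window_sigma_px
        Gaussian window standard deviation used for tensor smoothing.
    valid
        False where the tensor was degenerate or within the border band.
    """

    lambda_max: np.ndarray
    lambda_min: np.ndarray
    theta: np.ndarray
    coherence: np.ndarray
    window_sigma_px: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.theta.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.theta.shape


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 5:
        raise ValueError("image must be 2-D and at least 5x5")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    return image


def compute_gradients(
    image: np.ndarray, method: str = "cubic_spline"
) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives (d/dx, d/dy) of a 2-D image.

    ``cubic_spline`` differentiates the interpolating cubic B-spline at
    the pixel centres (prefilter to spline coefficients, then a central
    difference of the coefficients — the exact derivative of the spline
    at integer positions).  ``central_difference`` is the plain
    second-order finite difference, kept as an independent cross-check.
    """
    image = _check_image(image)
    if method == "cubic_spline":
        # derivative of the cubic B-spline: B3'(+-1) = -+1/2, B3'(0) = 0
        cx = ndimage.spline_filter1d(image, order=3, axis=1, mode="reflect")
        gx = ndimage.correlate1d(cx, [-0.5, 0.0, 0.5], axis=1, mode="reflect")
        cy = ndimage.spline_filter1d(image, order=3, axis=0, mode="reflect")
        gy = ndimage.correlate1d(cy, [-0.5, 0.0, 0.5], axis=0, mode="reflect")
    elif method == "central_difference":
        gy, gx = np.gradient(image)
    else:
        raise ValueError(f"unknown gradient method: {method!r}")
    return gx, gy


def structure_tensor_field(
    gradients: tuple[np.ndarray, np.ndarray], window_sigma_px: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-windowed tensor components (Jxx, Jxy, Jyy).

    Jxx = G_sigma * gx^2, Jxy = G_sigma * (gx gy), Jyy = G_sigma * gy^2,
    with reflective border handling.
    """
    if window_sigma_px <= 0:
        raise ValueError("window_sigma_px must be positive")
    gx, gy = gradients
    smooth = lambda a: ndimage.gaussian_filter(a, window_sigma_px, mode="reflect")
    return smooth(gx * gx), smooth(gx * gy), smooth(gy * gy)


def eigen_orientation(
    jxx: np.ndarray,
    jxy: np.ndarray,
    jyy: np.ndarray,
    window_sigma_px: float = float("nan"),
) -> OrientationField:
    """Closed-form eigendecomposition of per-pixel 2x2 symmetric tensors.

    theta is the angle of the eigenvector belonging to ``lambda_max``,
    reduced to [0, 180).  Degenerate pixels (both eigenvalues ~ 0, or
    equal eigenvalues) get theta = 0, coherence = 0 and are flagged
    invalid.
    """
    jxx, jxy, jyy = (np.asarray(a, dtype=np.float64) for a in (jxx, jxy, jyy))
    if not jxx.shape == jxy.shape == jyy.shape:
        raise ValueError("tensor component fields must share a shape")
    half_trace = 0.5 * (jxx + jyy)
    root = np.sqrt((0.5 * (jxx - jyy)) ** 2 + jxy**2)
    lmax = half_trace + root
    lmin = half_trace - root
    # numerical negative eigenvalues from a PSD product are rounding noise
    lmin = np.where((lmin < 0) & (lmin > -1e-9 * np.maximum(lmax, 1.0)), 0.0, lmin)

    theta = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    theta = np.mod(theta, 180.0)

    degenerate = (lmax + np.abs(lmin)) <= DEGENERATE_EPS
    isotropic = root <= DEGENERATE_EPS * np.maximum(np.abs(half_trace), 1.0)
    bad = degenerate | isotropic
    theta = np.where(bad, 0.0, theta)

    coherence = coherence_of(lmax, lmin)
    coherence = np.where(bad, 0.0, coherence)
    return OrientationField(
        lambda_max=lmax,
        lambda_min=lmin,
        theta=theta,
        coherence=coherence,
        window_sigma_px=window_sigma_px,
        valid=~bad,
    )


def coherence_of(lambda_max, lambda_min):
    """Coherence C = (lmax - lmin) / (lmax + lmin), elementwise.

    Returns 0 where the eigenvalue sum is below the degeneracy epsilon.
    Raises on eigenvalues that are negative beyond numeric tolerance.
    """
    lmax = np.asarray(lambda_max, dtype=np.float64)
    lmin = np.asarray(lambda_min, dtype=np.float64)
    tol = 1e-9 * np.maximum(np.abs(lmax).max(initial=1.0), 1.0)
    if np.any(lmin < -tol) or np.any(lmax < -tol):
        raise ValueError("eigenvalues must be non-negative")
    lmin = np.clip(lmin, 0.0, None)
    lmax = np.clip(lmax, 0.0, None)
    total = lmax + lmin
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(total > DEGENERATE_EPS, (lmax - lmin) / np.where(total > 0, total, 1.0), 0.0)
    return np.clip(c, 0.0, 1.0) if c.ndim else float(np.clip(c, 0.0, 1.0))


def mean_axial_orientation(theta_deg, weights=None) -> float:
    """Weighted mean of axial angles (degrees, [0, 180)) via angle doubling.

    Returns 0.5 * atan2(sum w sin 2t, sum w cos 2t) reduced to [0, 180).
    If the doubled-angle resultant vanishes (e.g. equal weight on 0 and
    90 degrees) the mean is undefined; 0 is returned with a warning.
    """
    theta = np.asarray(theta_deg, dtype=np.float64).ravel()
    if weights is None:
        w = np.ones_like(theta)
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
    if theta.size == 0 or w.size != theta.size:
        raise ValueError("theta and weights must be non-empty and equal length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with at least one positive")
    doubled = np.radians(2.0 * theta)
    s = float(np.sum(w * np.sin(doubled)))
    c = float(np.sum(w * np.cos(doubled)))
    if np.hypot(s, c) <= 1e-9 * float(np.sum(w)):
        warnings.warn(
            "axial mean undefined (zero resultant); returning 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.mod(0.5 * np.degrees(np.arctan2(s, c)), 180.0))


def orientation_field(
    image: np.ndarray,
    window_sigma_px: float = 1.0,
    gradient_method: str = "cubic_spline",
    border_margin_sigmas: float = 3.0,
) -> OrientationField:
    """Texture orientation/coherence map of a 2-D intensity image.

    The gradient structure tensor's dominant eigenvector points across
    the texture (along the intensity gradient); the reported theta is
    the texture axis itself, i.e. the eigenvector of the *smallest*
    gradient eigenvalue.  This is obtained by decomposing the adjugate
    tensor (Jyy, -Jxy, Jxx), which has the same eigenvalues with the
    eigenvectors swapped, so ``lambda_max``/``lambda_min``/coherence are
    those of the gradient tensor while theta follows the stripes.

    Pixels within ``border_margin_sigmas * window_sigma_px + 2`` of the
    border are flagged invalid (smoothing support is incomplete there).
    """
    grads = compute_gradients(image, method=gradient_method)
    jxx, jxy, jyy = structure_tensor_field(grads, window_sigma_px)
    fld = eigen_orientation(jyy, -jxy, jxx, window_sigma_px=window_sigma_px)
    margin = int(np.ceil(border_margin_sigmas * window_sigma_px)) + 2
    border = np.zeros(fld.shape, dtype=bool)
    if margin > 0:
        border[:] = True
        if fld.shape[0] > 2 * margin and fld.shape[1] > 2 * margin:
            border[margin:-margin, margin:-margin] = False
    fld.valid &= ~border
    return fld
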