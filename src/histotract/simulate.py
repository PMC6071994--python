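"""Stochastic anisotropic NSC migration simulator.

Paths start at uniform random points in a circular seeding region.  At
each step the walker advances a fixed step length:

* in white matter it follows the local orientation axis of a
  structure-tensor field computed with a wide (default 5 px sigma)
  Gaussian window, with the axial sign chosen to persist with the
  previous direction;
* in grey matter the heading turns by a random angle whose magnitude is
  uniform on [0, 180) degrees (sign equiprobable by default).

A path terminates when it revisits a previously occupied 1-px grid
cell (self-intersection), leaves the brain/image, or reaches the step
budget.  Everything is reproducible from the RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spatial import DEFAULT_PIXEL_SCALE_UM, TissueMasks
from .tensor import OrientationField

__all__ = [
    "SimConfig",
    "MigrationPath",
    "draw_seeds",
    "gm_turn",
    "next_step",
    "simulate_paths",
    "path_statistics",
]


@dataclass
class SimConfig:
    """Parameters of a simulation run (defaults follow the method)."""

    seed_center: tuple[float, float] = (0.0, 0.0)
    seed_radius_px: float = 20.0
    n_paths: int = 500
    step_px: float = 1.0
    max_steps: int = 5000
    wm_kernel_sigma_px: float = 5.0
    rng_seed: int = 0
    persistence: str = "forward"  # WM axial sign rule
    gm_turn_mode: str = "symmetric"  # 'symmetric' (+-U(0,180)) or 'one_sided'
    self_intersection: bool = True  # truncate on grid-cell revisit

    def __post_init__(self) -> None:
        if self.n_paths < 1 or self.max_steps < 1 or self.step_px <= 0:
            raise ValueError("n_paths >= 1, max_steps >= 1, step_px > 0 required")
        if self.gm_turn_mode not in ("symmetric", "one_sided"):
            raise ValueError("gm_turn_mode must be 'symmetric' or 'one_sided'")


@dataclass
class MigrationPath:
    """One simulated path and its termination bookkeeping."""

    points: np.ndarray  # (n, 2) xy
    terminated_by: str  # 'self_intersection' | 'max_steps' | 'boundary'
    steps_in_wm: int = 0
    steps_in_gm: int = 0

    @property
    def n_steps(self) -> int:
        return self.points.shape[0] - 1

    @property
    def net_displacement_px(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    @property
    def path_length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


def draw_seeds(
    config: SimConfig, image_shape: tuple[int, int], rng: np.random.Generator | None = None
) -> np.ndarray:
    """Uniform random points in the seeding disk (deterministic per seed)."""
    h, w = image_shape
    cx, cy = config.seed_center
    r = config.seed_radius_px
    if r < 0 or cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
        raise ValueError("seed disk must lie inside the image")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    radii = r * np.sqrt(rng.uniform(0.0, 1.0, config.n_paths))
    angles = rng.uniform(0.0, 2.0 * np.pi, config.n_paths)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def gm_turn(rng: np.random.Generator, mode: str = "symmetric") -> float:
    """Grey-matter turning angle (degrees) relative to the previous heading.

    ``symmetric``: magnitude uniform on [0, 180), sign equiprobable —
    an isotropic reorientation.  ``one_sided``: the literal signed angle
    uniform on [0, 180).
    """
    magnitude = rng.uniform(0.0, 180.0)
    if mode == "one_sided":
        return magnitude
    return magnitude if rng.integers(2) else -magnitude


def next_step(
    position: tuple[float, float],
    previous_direction: np.ndarray,
    fld: OrientationField,
    masks: TissueMasks,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit direction for the next step from ``position``.

    WM pixels with a valid orientation follow the local axis, sign kept
    consistent with the previous direction (nonnegative dot product).
    GM pixels — and WM pixels with a degenerate tensor — use the random
    turning rule.
    """
    ix = int(round(position[0]))
    iy = int(round(position[1]))
    in_wm = masks.wm[iy, ix]
    if in_wm and fld.valid[iy, ix]:
        t = np.radians(fld.theta[iy, ix])
        d = np.array([np.cos(t), np.sin(t)])
        if float(d @ previous_direction) < 0.0:
            d = -d
        return d
    prev_angle = np.arctan2(previous_direction[1], previous_direction[0])
    turn = np.radians(gm_turn(rng, config.gm_turn_mode))
    return np.array([np.cos(prev_angle + turn), np.sin(prev_angle + turn)])


def simulate_paths(
    fld: OrientationField, masks: TissueMasks, config: SimConfig
) -> list[MigrationPath]:
    """Simulate ``n_paths`` migration paths (bit-reproducible per rng_seed).

    Consecutive points are exactly ``step_px`` apart.  Self-intersection
    is detected on a per-path occupancy grid of rounded 1-px cells: a
    step landing on a previously visited cell (other than the current
    one) terminates the path.  Leaving the image or the brain mask
    terminates with cause 'boundary'.
    """
    h, w = masks.shape
    rng = np.random.default_rng(config.rng_seed)
    seeds = draw_seeds(config, (h, w), rng)
    paths: list[MigrationPath] = []
    for p in range(config.n_paths):
        pos = seeds[p].copy()
        theta0 = rng.uniform(0.0, 2.0 * np.pi)  # random initial heading
        direction = np.array([np.cos(theta0), np.sin(theta0)])
        points = [pos.copy()]
        cell = (int(round(pos[0])), int(round(pos[1])))
        visited = {cell}
        cause = "max_steps"
        wm_steps = gm_steps = 0
        for _ in range(config.max_steps):
            ix, iy = cell
            if not (0 <= ix < w and 0 <= iy < h) or not masks.brain[iy, ix]:
                cause = "boundary"
                break
            direction = next_step(pos, direction, fld, masks, config, rng)
            new_pos = pos + config.step_px * direction
            nix, niy = int(round(new_pos[0])), int(round(new_pos[1]))
            if not (0 <= nix < w and 0 <= niy < h) or not masks.brain[niy, nix]:
                cause = "boundary"
                break
            new_cell = (nix, niy)
            revisit = new_cell != cell and new_cell in visited
            pos = new_pos
            points.append(pos.copy())
            if masks.wm[niy, nix]:
                wm_steps += 1
            else:
                gm_steps += 1
            if revisit and config.self_intersection:
                cause = "self_intersection"
                break
            visited.add(new_cell)
            cell = new_cell
        paths.append(
            MigrationPath(
                points=np.asarray(points),
                terminated_by=cause,
                steps_in_wm=wm_steps,
                steps_in_gm=gm_steps,
            )
        )
    return paths


def path_statistics(
    paths: list[MigrationPath],
    masks: TissueMasks | None = None,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
) -> dict:
    """Pooled summary of a path ensemble (order-invariant)."""
    if not paths:
        raise ValueError("path list is empty")
    # sorted before reduction so the summary is order-invariant bit-for-bit
    net = np.sort([p.net_displacement_px for p in paths])
    length = np.sort([p.path_length_px for p in paths])
    wm = sum(p.steps_in_wm for p in paths)
    gm = sum(p.steps_in_gm for p in paths)
    total = wm + gm
    causes: dict[str, int] = {}
    for p in paths:
        causes[p.terminated_by] = causes.get(p.terminated_by, 0) + 1
    return {
        "n_paths": len(paths),
        "mean_net_displacement_um": float(net.mean() * pixel_scale_um),
        "mean_path_length_um": float(length.mean() * pixel_scale_um),
        "percent_steps_in_wm": float(100.0 * wm / total) if total else float("nan"),
        "termination_causes": dict(sorted(causes.items())),
        "total_steps": int(total),
    }
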