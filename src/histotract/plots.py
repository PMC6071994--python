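"""Figure rendering: CPD curves, orientation scatter, path overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .regression import RegressionResult
from .simulate import MigrationPath
from .spatial import CPDResult
from .tensor import OrientationField


def plot_cpd(cpd: CPDResult, path, title: str = "Distance CPD") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(cpd.distances_um, cpd.cum_prob, where="post")
    ax.axvline(cpd.median_um, color="crimson", ls="--", lw=1,
               label=f"median {cpd.median_um:.0f} µm")
    ax.set_xlabel("distance (µm)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_orientation_scatter(result: RegressionResult, path) -> None:
    """theta_NSC vs theta_WM with the weighted fit line."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if result.available and len(result.pairs):
        x, y = result.pairs[:, 0], result.pairs[:, 1]
        sizes = 10 + 40 * result.weights_used / result.weights_used.max()
        ax.scatter(x, y, s=sizes, alpha=0.6, edgecolor="k", linewidth=0.3)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, result.slope * grid + result.intercept, "r-",
                label=f"slope {result.slope:.2f}, r² {result.r_squared:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel(r"$\theta_{WM}$ (deg)")
    ax.set_ylabel(r"$\theta_{NSC}$ (deg)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_paths_overlay(
    paths: list[MigrationPath], fld: OrientationField, path, max_paths: int = 500
) -> None:
    """Migration paths drawn over the coherence map."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(fld.coherence, cmap="gray", vmin=0, vmax=1)
    for p in paths[:max_paths]:
        ax.plot(p.points[:, 0], p.points[:, 1], lw=0.4, alpha=0.5, color="orange")
    if paths:
        ax.plot(*paths[0].points[0], "c.", ms=4)
    ax.set_xlim(0, fld.shape[1])
    ax.set_ylim(fld.shape[0], 0)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
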