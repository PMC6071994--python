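"""End-to-end orchestration: phantom -> orientation -> clusters -> stats.

A :class:`RunConfig` fully determines every output byte; `run_pipeline`
executes the stages in dependency order and writes a manifest JSON with
a SHA-256 content hash per artifact, so determinism can be checked by
hash equality of two runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import io as htio
from . import regression as rg
from . import simulate as sim
from . import spatial as sp
from . import synthetic as syn
from . import tensor as st

logger = logging.getLogger(__name__)

_HEADER_NOTE = (
    "# coordinates: origin top-left, x rightward, y downward, 0-based pixel centers\n"
    "# angles: degrees, axial on [0,180), from the positive x axis\n"
)


@dataclass
class RunConfig:
    """All pipeline parameters, with method defaults."""

    # inputs: either image paths or a phantom spec
    dii_path: str | None = None
    nsc_path: str | None = None
    phantom_size: tuple[int, int] = (384, 384)
    tract_kind: str = "arc"
    tract_params: dict = field(
        default_factory=lambda: {
            "cx": 150.0, "cy": 192.0, "radius": 170.0, "angle0": -70.0, "angle1": 70.0,
        }
    )
    tract_halfwidth_px: float = 18.0
    texture_period_px: float = 8.0
    n_clusters: int = 14
    alignment: float = 1.0
    center_jitter_px: float = 4.0
    cluster_size_px: float = 100.0
    injection_site: tuple[float, float] | None = None
    pixel_scale_um: float = sp.DEFAULT_PIXEL_SCALE_UM

    # stage parameters (method defaults)
    dilate_px: float = cl.DEFAULT_DILATE_PX
    erode_px: float = cl.DEFAULT_ERODE_PX
    coalesce_on_masks: bool = False
    circularity_max: float = cl.DEFAULT_CIRCULARITY_MAX
    exclusion_radius_px: float = sp.DEFAULT_EXCLUSION_RADIUS_PX
    map_sigma_px: float = 1.0
    sim_sigma_px: float = 5.0
    n_paths: int = 500
    sim_step_px: float = 1.0
    sim_max_steps: int = 2000
    seed_radius_px: float = 20.0
    wm_radius_px: float = rg.DEFAULT_WM_RADIUS_PX
    coherence_min: float = rg.DEFAULT_COHERENCE_MIN
    wrap_mode: str = "align"
    # phantom blobs are half-max thresholded; use "otsu" for stained images
    cluster_threshold: str | float = 0.5
    min_cluster_size_px: int = 5

    out_dir: str = "histotract_out"
    make_plots: bool = True
    rng_seed: int = 0
    log_level: str = "INFO"


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML key-value config; unknown keys are rejected.

    Missing keys fall back to the method defaults (dilate 200, erode
    100, n_paths 500, pixel scale 1.444 um/px, ...).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    unknown = set(data) - _VALID_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s): {sorted(unknown)}; valid keys: {sorted(_VALID_KEYS)}"
        )
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in ("phantom_size", "injection_site") and value is not None:
            value = tuple(value)
        kwargs[f.name] = value
    config = RunConfig(**kwargs)
    logger.info("resolved config: %s", dataclasses.asdict(config))
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE)
        frame.to_csv(fh, index=False, float_format="%.6g")


def _get_inputs(config: RunConfig):
    """Phantom generation or image loading, returning a uniform bundle."""
    if config.dii_path is not None:
        dii = htio.read_image(config.dii_path)
        if config.nsc_path is None:
            raise RuntimeError("clusters stage: NSC image path is missing")
        nsc = htio.read_image(config.nsc_path)
        if config.injection_site is None:
            raise RuntimeError("distances stage: injection_site required for image inputs")
        return dii, nsc, None, config.injection_site
    tract = syn.TractSpec(config.tract_kind, dict(config.tract_params))
    phantom = syn.make_tract_phantom(
        config.phantom_size,
        tract,
        config.tract_halfwidth_px,
        config.texture_period_px,
        seed=config.rng_seed,
        pixel_scale_um=config.pixel_scale_um,
    )
    sizes = np.full(config.n_clusters, config.cluster_size_px)
    syn.plant_clusters(
        phantom,
        config.n_clusters,
        config.alignment,
        config.center_jitter_px,
        sizes,
        seed=config.rng_seed + 1,
    )
    injection = config.injection_site or phantom.injection_site
    return phantom.dii_image, phantom.nsc_image, phantom, injection


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the artifact manifest (also written).

    Any stage failure raises RuntimeError naming the stage; artifacts
    written so far stay on disk next to a ``FAILED`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    artifacts: dict[str, str] = {}
    stage = "inputs"
    try:
        dii, nsc, phantom, injection = _get_inputs(config)
        if phantom is not None:
            artifacts.update(htio.write_phantom(phantom, out / "phantom"))

        stage = "orientation"
        fld = st.orientation_field(dii, config.map_sigma_px)
        htio.write_map_tiff(out / "orientation_deg.tif", fld.theta)
        htio.write_map_tiff(out / "coherence.tif", fld.coherence)
        artifacts["orientation_map"] = str(out / "orientation_deg.tif")
        artifacts["coherence_map"] = str(out / "coherence.tif")
        _write_csv(
            out / "orientation_summary.csv",
            pd.DataFrame(
                [
                    {
                        "window_sigma_px": config.map_sigma_px,
                        "mean_coherence": float(fld.coherence[fld.valid].mean()),
                        "modal_orientation_deg": st.mean_axial_orientation(
                            fld.theta[fld.valid], fld.coherence[fld.valid]
                        ),
                        "valid_fraction": float(fld.valid.mean()),
                    }
                ]
            ),
        )
        artifacts["orientation_summary"] = str(out / "orientation_summary.csv")

        stage = "masks"
        if phantom is not None:
            masks = phantom.masks
        else:
            masks = sp.wm_mask_from_dii(dii, pixel_scale_um=config.pixel_scale_um)

        stage = "clusters"
        if nsc is None:
            raise ValueError("NSC image is missing")
        detected = cl.detect_clusters(nsc, config.cluster_threshold, config.min_cluster_size_px)
        detected.tissue_class = [masks.tissue_class_at(x, y) for x, y in detected.centers]
        regions = cl.coalesce(
            detected,
            dii.shape,
            config.dilate_px,
            config.erode_px,
            use_cluster_masks=config.coalesce_on_masks,
        )
        cl.assign_cluster_orientations(detected, regions, config.circularity_max)

        stage = "distances"
        dist_um, excluded = sp.distances_from_injection(
            detected.centers,
            injection,
            config.exclusion_radius_px,
            config.pixel_scale_um,
            image_shape=dii.shape,
        )
        iface_um = sp.interface_distances(detected.centers, masks, config.pixel_scale_um)
        cluster_table = pd.DataFrame(
            {
                "x_px": detected.centers[:, 0],
                "y_px": detected.centers[:, 1],
                "size_px": detected.sizes,
                "tissue_class": detected.tissue_class,
                "region_id": detected.region_id,
                "theta_nsc_deg": detected.theta_nsc,
                "region_circularity": [
                    regions[r - 1].circularity if r > 0 else np.nan
                    for r in detected.region_id
                ],
                "injection_distance_um": dist_um,
                "interface_distance_um": iface_um,
                "excluded_by_radius": excluded,
            }
        )
        _write_csv(out / "clusters.csv", cluster_table)
        artifacts["clusters"] = str(out / "clusters.csv")

        retained = ~excluded
        summary = {
            "pixel_scale_um": config.pixel_scale_um,
            "n_clusters": int(len(detected)),
            "n_excluded_by_radius": int(excluded.sum()),
        }
        if retained.any():
            cpd = sp.weighted_cpd(dist_um[retained], detected.sizes[retained])
            _write_csv(
                out / "cpd_injection.csv",
                pd.DataFrame(
                    {"distance_um": cpd.distances_um, "cum_prob": cpd.cum_prob}
                ),
            )
            artifacts["cpd_injection"] = str(out / "cpd_injection.csv")
            summary["median_injection_distance_um"] = cpd.median_um
            if config.make_plots:
                from . import plots

                plots.plot_cpd(cpd, out / "cpd_injection.png", "Injection-site distance CPD")
                artifacts["cpd_injection_plot"] = str(out / "cpd_injection.png")
        icpd = sp.weighted_cpd(iface_um, detected.sizes)
        _write_csv(
            out / "cpd_interface.csv",
            pd.DataFrame({"distance_um": icpd.distances_um, "cum_prob": icpd.cum_prob}),
        )
        artifacts["cpd_interface"] = str(out / "cpd_interface.csv")
        summary["median_interface_distance_um"] = icpd.median_um
        summary["wm_percent"] = sp.wm_fraction(detected.centers, detected.sizes, masks)
        (out / "distance_summary.json").write_text(json.dumps(summary, indent=2))
        artifacts["distance_summary"] = str(out / "distance_summary.json")

        stage = "correlate"
        results = rg.correlate_by_tissue(
            detected,
            regions,
            fld,
            masks,
            config.wm_radius_px,
            config.coherence_min,
            config.wrap_mode,
        )
        pairs, weights, tissue, idx = rg.build_orientation_pairs(
            detected, regions, fld, config.wm_radius_px, config.coherence_min,
            config.wrap_mode,
        )
        _write_csv(
            out / "orientation_pairs.csv",
            pd.DataFrame(
                {
                    "theta_wm_deg": pairs[:, 0] if len(pairs) else [],
                    "theta_nsc_deg": pairs[:, 1] if len(pairs) else [],
                    "weight": weights,
                    "tissue_class": tissue,
                    "region_id": [int(detected.region_id[i]) for i in idx],
                }
            ),
        )
        artifacts["orientation_pairs"] = str(out / "orientation_pairs.csv")
        regression_json = {
            name: (
                {
                    "slope": res.slope,
                    "intercept_deg": res.intercept,
                    "r_squared": res.r_squared,
                    "n": res.n_points,
                }
                if res.available
                else None
            )
            for name, res in results.items()
        }
        (out / "regression.json").write_text(json.dumps(regression_json, indent=2))
        artifacts["regression"] = str(out / "regression.json")
        if config.make_plots and results["all"].available:
            from . import plots

            plots.plot_orientation_scatter(results["all"], out / "orientation_scatter.png")
            artifacts["orientation_scatter_plot"] = str(out / "orientation_scatter.png")

        stage = "simulate"
        sim_field = st.orientation_field(dii, config.sim_sigma_px)
        h, w = dii.shape
        seed_center = (
            float(np.clip(injection[0], config.seed_radius_px, w - 1 - config.seed_radius_px)),
            float(np.clip(injection[1], config.seed_radius_px, h - 1 - config.seed_radius_px)),
        )
        sim_config = sim.SimConfig(
            seed_center=seed_center,
            seed_radius_px=config.seed_radius_px,
            n_paths=config.n_paths,
            step_px=config.sim_step_px,
            max_steps=config.sim_max_steps,
            wm_kernel_sigma_px=config.sim_sigma_px,
            rng_seed=config.rng_seed,
        )
        paths = sim.simulate_paths(sim_field, masks, sim_config)
        rows = []
        for pid, p in enumerate(paths):
            for step, (x, y) in enumerate(p.points):
                rows.append((pid, step, x, y))
        _write_csv(
            out / "paths.csv",
            pd.DataFrame(rows, columns=["path_id", "step", "x_px", "y_px"]),
        )
        artifacts["paths"] = str(out / "paths.csv")
        stats = sim.path_statistics(paths, masks, config.pixel_scale_um)
        (out / "simulation_summary.json").write_text(json.dumps(stats, indent=2))
        artifacts["simulation_summary"] = str(out / "simulation_summary.json")
        if config.make_plots:
            from . import plots

            plots.plot_paths_overlay(paths, sim_field, out / "paths_overlay.png")
            artifacts["paths_overlay_plot"] = str(out / "paths_overlay.png")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
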