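"""Reading and writing of images, masks and phantom sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def read_image(path, channel: str | int = "luminance") -> np.ndarray:
    """Load a TIFF/PNG image as float64 in [0, 1].

    RGB inputs are reduced by ``channel``: an index (0/1/2) selects one
    channel, ``'luminance'`` takes the Rec.601 weighted mean.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if isinstance(channel, int):
            arr = arr[..., channel]
        else:
            arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr


def write_map_tiff(path, array: np.ndarray) -> None:
    """Write a float field (orientation/coherence map) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(array, dtype=np.float32))


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major, starts with zeros)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(encoded: dict) -> np.ndarray:
    shape = tuple(encoded["shape"])
    runs = encoded["runs"]
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for r in runs:
        if value:
            out[pos : pos + r] = True
        pos += r
        value = not value
    return out.reshape(shape)


def write_phantom(phantom, out_dir) -> dict:
    """Write a phantom as two TIFF channels plus a JSON sidecar.

    Returns the manifest-style dict of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dii_path = out_dir / "dii.tif"
    nsc_path = out_dir / "nsc.tif"
    write_map_tiff(dii_path, phantom.dii_image)
    write_map_tiff(nsc_path, phantom.nsc_image)
    sidecar = {
        "coordinate_convention": "origin top-left, x rightward, y downward, 0-based",
        "pixel_scale_um": phantom.pixel_scale_um,
        "injection_site_xy": list(phantom.injection_site),
        "seed": phantom.seed,
        "tract_centerline_xy": np.round(phantom.tract_centerline, 3).tolist(),
        "tract_tangent_deg": np.round(phantom.tract_tangent_deg, 3).tolist(),
        "truth_cluster_angles_deg": np.round(phantom.truth_cluster_angles, 3).tolist(),
        "wm_mask_rle": rle_encode(phantom.masks.wm),
        "gm_mask_rle": rle_encode(phantom.masks.gm),
    }
    sidecar_path = out_dir / "phantom.json"
    sidecar_path.write_text(json.dumps(sidecar))
    return {"dii": str(dii_path), "nsc": str(nsc_path), "sidecar": str(sidecar_path)}
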