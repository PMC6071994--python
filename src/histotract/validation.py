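"""Standard phantom protocols used for end-to-end validation.

These fix the phantom geometry and stage parameters used when checking
that the full pipeline recovers planted ground truth (orientation
recovery, alignment-slope recovery, distance round trips), so the test
suite and the acceptance report run the identical computation.

The recovery phantom is a 640x640 section with a circular-arc tract
(tangents spanning ~[20, 160) degrees, clear of the 0/180 wrap) and
well-separated elongated clusters, analyzed with mask-based coalescing
at phantom scale (the 200/100 px disks of full-scale slides would merge
every cluster on a desk-scale image) and raw-angle regression.
"""

from __future__ import annotations

import numpy as np

from . import clusters as cl
from . import regression as rg
from . import synthetic as syn
from . import tensor as st

RECOVERY_SIZE = (640, 640)
RECOVERY_TRACT = dict(cx=200.0, cy=320.0, radius=290.0, angle0=-70.0, angle1=70.0)
RECOVERY_HALFWIDTH_PX = 18.0
RECOVERY_N_CLUSTERS = 17
RECOVERY_CLUSTER_SIZE_PX = 120.0
RECOVERY_JITTER_PX = 4.0
RECOVERY_DILATE_PX = 4.0
RECOVERY_ERODE_PX = 2.0
RECOVERY_WM_RADIUS_PX = 12.0


def recovery_phantom(seed: int, alignment: float):
    """Arc-tract phantom with planted clusters for recovery runs."""
    tract = syn.TractSpec("arc", dict(RECOVERY_TRACT))
    phantom = syn.make_tract_phantom(
        RECOVERY_SIZE, tract, RECOVERY_HALFWIDTH_PX, seed=seed
    )
    planted = syn.plant_clusters(
        phantom,
        RECOVERY_N_CLUSTERS,
        alignment,
        RECOVERY_JITTER_PX,
        np.full(RECOVERY_N_CLUSTERS, RECOVERY_CLUSTER_SIZE_PX),
        seed=seed + 1000,
    )
    return phantom, planted


def alignment_recovery_run(seed: int, alignment: float) -> rg.RegressionResult:
    """Full pipeline pass: phantom -> detect -> coalesce -> theta_NSC ->
    theta_WM -> weighted regression over all clusters.

    Raw-angle regression (no axial pre-alignment) is used so that the
    slope attenuates toward 0 as planted alignment decreases; the arc
    tangent range stays inside (0, 180) so the raw representatives are
    continuous at full alignment.
    """
    phantom, _ = recovery_phantom(seed, alignment)
    detected = cl.detect_clusters(phantom.nsc_image, 0.5, 5)
    regions = cl.coalesce(
        detected,
        phantom.shape,
        RECOVERY_DILATE_PX,
        RECOVERY_ERODE_PX,
        use_cluster_masks=True,
    )
    detected.tissue_class = [
        phantom.masks.tissue_class_at(x, y) for x, y in detected.centers
    ]
    cl.assign_cluster_orientations(detected, regions, cl.DEFAULT_CIRCULARITY_MAX)
    fld = st.orientation_field(phantom.dii_image, 1.0)
    return rg.correlate_by_tissue(
        detected,
        regions,
        fld,
        wm_radius_px=RECOVERY_WM_RADIUS_PX,
        coherence_min=0.2,
        wrap_mode="raw",
    )["all"]


def theta_nsc_recovery_errors(seed: int) -> np.ndarray:
    """Axial |theta_NSC - truth| per recovered cluster at alignment 1."""
    phantom, planted = recovery_phantom(seed, 1.0)
    detected = cl.detect_clusters(phantom.nsc_image, 0.5, 5)
    regions = cl.coalesce(
        detected,
        phantom.shape,
        RECOVERY_DILATE_PX,
        RECOVERY_ERODE_PX,
        use_cluster_masks=True,
    )
    cl.assign_cluster_orientations(detected, regions, cl.DEFAULT_CIRCULARITY_MAX)
    errors = []
    for i in range(len(detected)):
        if not np.isfinite(detected.theta_nsc[i]):
            continue
        # match the detected cluster to the nearest planted center
        d = np.hypot(
            planted.centers[:, 0] - detected.centers[i, 0],
            planted.centers[:, 1] - detected.centers[i, 1],
        )
        truth = phantom.truth_cluster_angles[int(np.argmin(d))]
        diff = abs(float(detected.theta_nsc[i]) - truth) % 180.0
        errors.append(min(diff, 180.0 - diff))
    return np.asarray(errors)
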