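import numpy as np
import pytest

from histotract import synthetic
from histotract.spatial import TissueMasks
from histotract.tensor import OrientationField


def axial_diff(a, b):
    """Smallest axial angle difference in degrees."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)


@pytest.fixture(scope="session")
def line_phantom():
    """Straight horizontal tract in a 256x256 frame."""
    tract = synthetic.TractSpec("line", dict(x0=30.0, y0=128.0, x1=225.0, y1=128.0))
    return synthetic.make_tract_phantom((256, 256), tract, 24.0, 8.0, seed=11)


@pytest.fixture(scope="session")
def parabola_phantom():
    tract = synthetic.TractSpec(
        "parabola", dict(x_min=40.0, x_max=215.0, cx=128.0, y0=80.0, curv=0.004)
    )
    return synthetic.make_tract_phantom((256, 256), tract, 20.0, 8.0, seed=12)


def uniform_field(shape, theta_deg, coherence=1.0):
    """Constant-orientation OrientationField for simulator tests."""
    ones = np.ones(shape)
    return OrientationField(
        lambda_max=ones.copy(),
        lambda_min=np.zeros(shape),
        theta=np.full(shape, float(theta_deg)),
        coherence=np.full(shape, float(coherence)),
        window_sigma_px=1.0,
    )


def single_class_masks(shape, tissue="WM"):
    """TissueMasks that are entirely WM or entirely GM."""
    full = np.ones(shape, dtype=bool)
    empty = np.zeros(shape, dtype=bool)
    wm, gm = (full, empty) if tissue == "WM" else (empty, full)
    return TissueMasks(
        wm=wm,
        gm=gm,
        background=empty.copy(),
        interface_pixels=np.empty((0, 2)),
    )
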