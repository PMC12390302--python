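import numpy as np
import pytest

import nirfuse as nf


@pytest.fixture(scope="session")
def default_phantom():
    """The default seeded acquisition: 100 frames, 256x256, with ground truth."""
    scene = nf.default_scene(seed=0)
    stack, truth = nf.generate_stack(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def small_scene():
    """A reduced 3-band x 4-exposure scene for fast I/O and pipeline tests."""
    return nf.PhantomScene(
        image_h=64,
        image_w=64,
        disk_center=(32, 32),
        disk_diameter_px=20.0,
        band_cwls_nm=(713.0, 805.0, 920.0),
        band_relative_intensity=(1.0, 0.7, 0.4),
        scatter_sigma_px=(4.0, 3.0, 2.0),
        attenuation=(0.3, 0.55, 0.8),
        exposure_times_ms=(30.0, 150.0, 350.0, 650.0),
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def seam_fixture():
    """Two constant frames with a hard vertical weight boundary at mid-width.

    Returns (stack, wstack, seam_col): frame A (0.3) owns the left half,
    frame B (0.7) the right half.  Naive fusion produces a step at the
    seam; pyramid blending should smooth it out.
    """
    h = w = 64
    a = np.full((h, w), 0.3)
    b = np.full((h, w), 0.7)
    left = np.zeros((h, w))
    left[:, : w // 2] = 1.0
    stack = nf.ImageStack(np.stack([a, b]), [(713.0, 100.0), (920.0, 100.0)])
    wstack = nf.WeightStack(raw=[left, 1.0 - left], normalized=[left, 1.0 - left])
    return stack, wstack, w // 2


def max_seam_gradient(img: np.ndarray, seam_col: int, halfwidth: int = 4) -> float:
    """Largest horizontal intensity jump in a band around the seam column."""
    grad = np.abs(np.diff(img, axis=1))
    lo = max(seam_col - 1 - halfwidth, 0)
    hi = min(seam_col - 1 + halfwidth + 1, grad.shape[1])
    return float(grad[:, lo:hi].max())
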