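import numpy as np
import pytest

from callusct import PhantomSpec, make_fracture_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 128-cube fracture phantom with proportionally scaled anatomy."""
    spec = PhantomSpec(
        shape_vox=(128, 128, 128),
        cortex_outer_radius_mm=0.31,
        cortex_inner_radius_mm=0.22,
        callus_collar_thickness_mm=0.25,
        gap_halfwidth_mm=0.125,
        fragment_displacement_mm=0.06,
        noise_sd=0.0,
        seed=7,
    )
    vol, truth = make_fracture_phantom(spec)
    return spec, vol, truth


def dice(pred, truth, code):
    a = np.asarray(pred) == code
    b = np.asarray(truth) == code
    return 2 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def dice_fn():
    return dice
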