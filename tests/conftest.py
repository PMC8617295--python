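import numpy as np
import pytest

from gradpain.preprocess import clean
from gradpain.synthetic import PhantomSpec, make_phantom


def line_phantom_spec(noise_sd: float, seed: int = 0, n_roi: int = 500) -> PhantomSpec:
    """A 1-axis phantom: a line-shaped ROI in which every voxel has a distinct
    planted gradient value, flanked by the two target boxes."""
    return PhantomSpec(
        grid_shape=(n_roi + 16, 3, 3),
        roi_box=((8, 8 + n_roi), (1, 2), (1, 2)),
        target_box_a=((0, 6), (0, 3), (0, 3)),
        target_box_b=((n_roi + 10, n_roi + 16), (0, 3), (0, 3)),
        gradient_axis=0,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_line_phantom():
    """Noise-free cleaned line phantom: (volume, roi, brain, g)."""
    vol, roi, brain, g = make_phantom(line_phantom_spec(0.0, seed=0, n_roi=300))
    cvol, cmask = clean(vol, brain)
    return cvol, roi, cmask, g


@pytest.fixture(scope="session")
def clean_box_phantom():
    """Default-geometry phantom at default noise, cleaned."""
    spec = PhantomSpec(seed=11)
    vol, roi, brain, g = make_phantom(spec)
    cvol, cmask = clean(vol, brain)
    return spec, cvol, roi, cmask, g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
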