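import numpy as np
import pytest

from fishchain.model import DEFAULT_SPEC, build_pose
from fishchain.synthetic import SimConfig, render_silhouette, simulate


@pytest.fixture(scope="session")
def spec():
    return DEFAULT_SPEC


@pytest.fixture
def straight_pose(spec):
    """Axis-aligned pose pointing along +x, comfortably inside a canvas."""
    return build_pose((320, 120), np.zeros(spec.n_r), spec)


def render_fish_frame(pose, spec, shape, fish=40.0, plate=200.0,
                      noise_sigma=0.0, rng=None):
    """Grayscale frame of one tapered fish silhouette on a bright plate."""
    sil = render_silhouette(pose, spec, shape)
    img = np.where(sil, fish, plate)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        img = img + rng.normal(0.0, noise_sigma, shape)
    return img, sil


@pytest.fixture(scope="session")
def small_sim():
    """A short clean 3-fish sequence shared by the slower integration tests."""
    return simulate(SimConfig(n_fish=3, frames=60, arena=(1000, 1000), seed=11))
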