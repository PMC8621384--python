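import numpy as np
import pytest

from vesselx import PhantomSpec, make_tube, make_vessel_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tree_phantom():
    """One default vessel-tree phantom (image with fov, truth mask)."""
    return make_vessel_tree(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_tube():
    """Noise-free horizontal tube of radius 4 on a 256x256 canvas."""
    spec = PhantomSpec(noise_sigma=0.0)
    return make_tube(256, 256, 4.0, 0.0, spec)
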