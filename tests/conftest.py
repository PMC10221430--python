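import numpy as np
import pytest

from fundoseg.synthetic import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """One deterministic 96x96 scene with a mid-range CDR."""
    params = SceneParams(image_size=96, disc_radii=(22.0, 18.0), cdr_true=0.5,
                         vessel_count=2, noise_sd=4.0)
    return generate_scene(params, seed=7)


def random_binary_mask(rng, shape, p=0.3):
    return rng.random(shape) < p
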