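import numpy as np
import pytest

from pulmoseg import BinaryMask, PhantomSpec


@pytest.fixture
def small_spec():
    """A 128-px phantom with default contrast and noise."""
    return PhantomSpec(image_size=128, body_axes=(50.0, 57.0),
                       lung_axes=(27.0, 16.0), lung_offset=24.0, seed=7)


@pytest.fixture
def noiseless_spec(small_spec):
    from dataclasses import replace
    return replace(small_spec, sigma_noise=0.0, n_vessels=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(16, 16), p=0.5, nonempty=False):
    m = (rng.random(shape) < p).astype(np.uint8)
    if nonempty and m.sum() == 0:
        m[shape[0] // 2, shape[1] // 2] = 1
    return BinaryMask(m)
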