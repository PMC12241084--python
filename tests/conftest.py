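import numpy as np
import pytest

from ranet.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams.small(64)


@pytest.fixture(scope="session")
def phantom_pair(small_params):
    return generate_phantom(small_params, seed=7)


@pytest.fixture(scope="session")
def phantom_stack(small_params):
    """Eight seeded 64x64 phantom image/mask stacks."""
    pairs = [generate_phantom(small_params, seed=100 + i) for i in range(8)]
    X = np.stack([p.image.pixels for p in pairs])
    y = np.stack([p.mask.labels for p in pairs])
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(32, 32), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


def random_blob_mask(rng, side=24):
    """Connected blob mask (disc with jittered radius), sometimes empty."""
    from skimage.draw import disk

    m = np.zeros((side, side), dtype=np.uint8)
    r = rng.uniform(2, side / 3)
    cr, cc = rng.uniform(side * 0.25, side * 0.75, size=2)
    rr, cc_idx = disk((cr, cc), r, shape=m.shape)
    m[rr, cc_idx] = 1
    return m
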