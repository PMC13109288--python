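import numpy as np
import pytest

from ctnodes import CtVolume, LesionLabelMap, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom shared by read-only tests: volume, labels, intent table."""
    spec = PhantomSpec(shape=(32, 96, 96), node_count=8, seed=11)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_blob_mask(rng, shape=(12, 12, 12), n_seeds=3, growth=20):
    """Random connected-ish blob mask for metric oracle tests."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        z, y, x = (rng.integers(2, s - 2) for s in shape)
        mask[z, y, x] = True
    for _ in range(growth):
        z, y, x = (rng.integers(1, s - 1) for s in shape)
        if mask[max(0, z - 1):z + 2, max(0, y - 1):y + 2,
                max(0, x - 1):x + 2].any():
            mask[z, y, x] = True
    return mask
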