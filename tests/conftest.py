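import numpy as np
import pytest

from elene.io_preprocess import NodeImage
from elene.synthetic_data import PhantomSpec, TableSpec, generate_node, generate_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_node(default_spec):
    """One default-spec normal phantom, reused by read-only tests."""
    return generate_node(default_spec, "normal", seed=7)


@pytest.fixture(scope="session")
def ene_node(default_spec):
    return generate_node(default_spec, "ENE", seed=7)


@pytest.fixture(scope="session")
def ball_node():
    """Isotropic digital ball, radius 10 voxels."""
    z, y, x = np.mgrid[-14:15, -14:15, -14:15]
    mask = (x * x + y * y + z * z) <= 100
    vol = np.full(mask.shape, 128, dtype=np.uint8)
    return NodeImage(vol, mask, (1.0, 1.0, 1.0), node_id="ball")


@pytest.fixture(scope="session")
def planted_table():
    """Strong 3-informative-column table for selection tests."""
    return generate_table(TableSpec(n_per_class=50, p=30, k=3, effect=3.0,
                                    seed=11))


def random_blob(rng, shape=(24, 24), seed_points=4, dilations=5):
    """Random connected-ish blob mask away from the border."""
    from scipy import ndimage
    mask = np.zeros(shape, dtype=bool)
    rr = rng.integers(8, shape[0] - 8, size=seed_points)
    cc = rng.integers(8, shape[1] - 8, size=seed_points)
    mask[rr, cc] = True
    mask = ndimage.binary_dilation(mask, iterations=dilations)
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    return mask
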