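import numpy as np
import pytest

from edlseg.synthetic import generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 32x32 binary phantom shared across tests."""
    return generate_phantom(seed=7, shape=(32, 32), n_classes=2)


def random_alpha_labels(rng, k=None, n_voxels=None, alpha_max=8.0):
    """Random (alpha, one-hot label) pair on a flat voxel set."""
    k = int(k or rng.integers(2, 5))
    n_voxels = int(n_voxels or rng.integers(1, 5))
    alpha = rng.uniform(1.0, alpha_max, size=(k, n_voxels))
    labels = np.eye(k)[rng.integers(0, k, size=n_voxels)].T
    return alpha, labels
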