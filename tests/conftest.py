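import numpy as np
import pytest

from fclong.atlas import Atlas, default_atlas, network_partition


@pytest.fixture(scope="session")
def atlas264():
    return default_atlas()


@pytest.fixture(scope="session")
def partition264(atlas264):
    return network_partition(atlas264)


@pytest.fixture
def two_net_atlas():
    """Four ROIs in two networks: {0, 1} in network 0, {2, 3} in network 1."""
    centers = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0], [20, 20, 0]], float)
    return Atlas(centers_mm=centers, radii_mm=np.full(4, 5.0),
                 network_labels=np.array([0, 0, 1, 1]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
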