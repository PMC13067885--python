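import numpy as np
import pytest

from swaynet.roi_connectivity import default_channel_map


@pytest.fixture(scope="session")
def channel_map():
    return default_channel_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def exact_correlation_pair(rng, n, r):
    """Two length-n vectors whose sample Pearson correlation is exactly r.

    Gram–Schmidt in the sample inner product: center and normalize x, then
    orthogonalize and normalize an independent vector, and mix.
    """
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = x - x.mean()
    x = x / np.linalg.norm(x)
    e = e - e.mean()
    e = e - (e @ x) * x
    e = e / np.linalg.norm(e)
    y = r * x + np.sqrt(1 - r**2) * e
    return x, y
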