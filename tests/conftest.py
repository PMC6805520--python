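import numpy as np
import pytest

from weightscape import load_fixture


@pytest.fixture(scope="session")
def fx():
    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_simplex(rng, m):
    v = rng.dirichlet(np.ones(m))
    return v / v.sum()
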