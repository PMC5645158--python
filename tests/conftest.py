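import numpy as np
import pytest

from popmaxent import PairwiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pairwise(n, rng, h_loc=-1.0, h_scale=0.5, j_scale=0.25,
                    j_loc=0.0):
    """Random symmetric pairwise model for oracle tests."""
    h = rng.normal(h_loc, h_scale, n)
    J = np.triu(rng.normal(j_loc, j_scale, (n, n)), 1)
    J = J + J.T
    return PairwiseModel(h=h, J=J)


@pytest.fixture
def make_model(rng):
    def _make(n, **kw):
        return random_pairwise(n, rng, **kw)
    return _make
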