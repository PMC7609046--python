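import numpy as np
import pytest

from germsoma import make_topology


@pytest.fixture
def ring4():
    return make_topology("ring", 4)


@pytest.fixture
def ring10():
    return make_topology("ring", 10)


@pytest.fixture
def bipartite10():
    return make_topology("balanced_bipartite", 10)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
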