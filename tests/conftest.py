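import numpy as np
import pytest

from fragvlib import FixtureSpec, build_interface_graph, make_complex


@pytest.fixture
def small_complex():
    """Default synthetic complex: 24 receptor atoms, 4-atom ligand, 3 in
    contact with the receptor's bottom face."""
    return make_complex(FixtureSpec(seed=11))


@pytest.fixture
def small_graph(small_complex):
    return build_interface_graph(small_complex)


@pytest.fixture
def water_complex():
    return make_complex(FixtureSpec(seed=11, n_waters=2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
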