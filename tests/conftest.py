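import numpy as np
import pytest

from tunnelfold.cg import EnergyParams, build_topology
from tunnelfold.synthetic import make_toy_zincfinger, make_tunnel


@pytest.fixture(scope="session")
def toy():
    return make_toy_zincfinger()


@pytest.fixture(scope="session")
def tunnel():
    return make_tunnel()


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


@pytest.fixture(scope="session")
def free_domain(toy, params):
    """Toy domain alone (L=0, no environment), C-terminus tethered."""
    return build_topology(
        toy.positions, toy.sequence, 0, None,
        coordination=toy.coordination, params=params,
    )


@pytest.fixture(scope="session")
def tunnel_chain_26(toy, tunnel, params):
    return build_topology(
        toy.positions, toy.sequence, 26, tunnel,
        coordination=toy.coordination, params=params,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
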