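import numpy as np
import pytest

from tauleapx import LinearMomentOracle, load_system


@pytest.fixture(scope="session")
def decay():
    net, defaults = load_system("decay")
    return net, defaults


@pytest.fixture(scope="session")
def decay_oracle(decay):
    return LinearMomentOracle.from_network(decay[0])


@pytest.fixture(scope="session")
def chain5():
    net, defaults = load_system("chain5")
    return net, defaults


@pytest.fixture(scope="session")
def chain5_oracle(chain5):
    return LinearMomentOracle.from_network(chain5[0])


@pytest.fixture(scope="session")
def michaelis_menten():
    net, defaults = load_system("michaelis_menten")
    return net, defaults


@pytest.fixture(scope="session")
def schlogl():
    net, defaults = load_system("schlogl")
    return net, defaults


@pytest.fixture(scope="session")
def schlogl_cme(schlogl):
    """Truncated CME solution of the bistable system at T=5 (shared: ~40 s)."""
    from tauleapx import cme_solve

    net, defaults = schlogl
    lo, hi = defaults["cme_bounds"]
    return cme_solve(net, defaults["T"], lo, hi)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
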