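import numpy as np
import pytest

import drivernet as dn


@pytest.fixture(scope="session")
def small_topology():
    """100 E + 25 I random network with unit weights (session-wide, read-only)."""
    topo = dn.build_random_topology(100, 25, 0.05, seed=11)
    return dn.init_weights(topo, "constant", {"value": 1.0}, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
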