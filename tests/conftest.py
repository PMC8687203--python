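import numpy as np
import pytest

from citsens import Reaction, ReactionNetwork, build_fixture


@pytest.fixture(scope="session")
def decay_net():
    """Pure decay S -> 0 at rate c = 0.1, x0 = 100."""
    fx = build_fixture("pure_decay")
    return fx.net, fx.x0


@pytest.fixture(scope="session")
def iso_net():
    """Two-state isomerisation S1 <-> S2, c = (1, 1), x0 = (10, 0)."""
    fx = build_fixture("isomerisation")
    return fx.net, fx.x0


@pytest.fixture(scope="session")
def dd_fixture():
    return build_fixture("decay_dimer")


@pytest.fixture(scope="session")
def stiff_iso_net():
    """Fast isomerisation used for implicit-step stability checks."""
    reactions = [
        Reaction("R1", ((0, 1),), ((1, 1),), 1e5),
        Reaction("R2", ((1, 1),), ((0, 1),), 1e5),
    ]
    net = ReactionNetwork(["S1", "S2"], reactions, [(0, 1)])
    return net, np.array([10_000, 0], dtype=np.int64)
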