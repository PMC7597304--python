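import numpy as np
import pytest

from bnaf import network_core as nc


def make_fig1_like_net() -> nc.BooleanNetwork:
    """A 3-node network with three fixed points (000, 010, 111), the 2-cycle
    {011, 110}, and 100/101 inside the cycle's basin (states written v1v2v3)."""
    s = nc.state_from_string
    state_map = {
        s("000"): s("000"),
        s("010"): s("010"),
        s("111"): s("111"),
        s("011"): s("110"),
        s("110"): s("011"),
        s("100"): s("101"),
        s("101"): s("011"),
        s("001"): s("000"),
    }
    return nc.network_from_state_map(state_map, 3, node_names=("v1", "v2", "v3"))


def make_identity_net(n: int) -> nc.BooleanNetwork:
    """Each node copies itself: every state is a fixed point."""
    return nc.BooleanNetwork(
        tuple(f"v{i}" for i in range(n)),
        tuple((i,) for i in range(n)),
        tuple((0, 1) for _ in range(n)),
    )


def make_constant_zero_net(n: int, k: int = 1) -> nc.BooleanNetwork:
    """Every node updates to 0 regardless of input."""
    return nc.BooleanNetwork(
        tuple(f"v{i}" for i in range(n)),
        tuple(tuple(range(k)) for _ in range(n)),
        tuple(tuple([0] * (1 << k)) for _ in range(n)),
    )


@pytest.fixture
def fig1_net():
    return make_fig1_like_net()


@pytest.fixture
def identity3():
    return make_identity_net(3)


@pytest.fixture
def rbn_factory():
    def make(n=8, k=2, seed=0, bias=0.5):
        return nc.generate_rbn(nc.RBNConfig(n, k, seed, bias))

    return make


def oracle_step(net: nc.BooleanNetwork, state: int) -> int:
    """Independent synchronous update: bit-by-bit, no vectorized code shared
    with the package's step implementation."""
    nxt = 0
    for i in range(net.N):
        row = 0
        for inp in net.inputs[i]:  # first input = most significant row bit
            row = row * 2 + ((state >> inp) & 1)
        if net.truth_tables[i][row]:
            nxt |= 1 << i
    return nxt


def oracle_attractors(net: nc.BooleanNetwork):
    """Brute-force per-state convergence: iterate each initial state until a
    state repeats, then read off the cycle. Returns (set of frozenset cycles,
    dict cycle -> basin size)."""
    basins: dict[frozenset, int] = {}
    for start in range(1 << net.N):
        seen = {}
        path = []
        x = start
        while x not in seen:
            seen[x] = len(path)
            path.append(x)
            x = oracle_step(net, x)
        cycle = frozenset(path[seen[x]:])
        basins[cycle] = basins.get(cycle, 0) + 1
    return set(basins), basins
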