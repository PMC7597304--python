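"""Exhaustive attractor and basin-of-attraction enumeration.

Every one of the 2^N states is traced to its attractor, so the result is
exact: the number of attractors, their cycle states, and basin sizes. A node
cap (default 26) guards against state-space explosion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SizeLimitError
from .network_core import BooleanNetwork, transition_table

__all__ = [
    "Attractor",
    "StateSpaceAnalysis",
    "find_attractors",
    "attractor_count",
    "mean_attractor_length",
    "normalized_basin_entropy",
]

DEFAULT_NODE_CAP = 26


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length 1) or limit cycle of the synchronous update map.

    ``states`` is the cycle in transition order, rotated to start at the
    smallest integer-encoded state; that smallest state is ``canonical_key``.
    """

    states: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def canonical_key(self) -> int:
        return self.states[0]

    @property
    def state_set(self) -> frozenset[int]:
        return frozenset(self.states)


@dataclass(frozen=True)
class StateSpaceAnalysis:
    """Complete attractor landscape of one network.

    ``basin_sizes`` maps each attractor's canonical key to the number of
    states converging to it (attractor states included); sizes sum to 2^N.
    """

    attractors: tuple[Attractor, ...]
    basin_sizes: dict[int, int]
    N: int

    @property
    def attractor_keys(self) -> frozenset[frozenset[int]]:
        """Attractor identities as state sets (rotation-independent)."""
        return frozenset(a.state_set for a in self.attractors)

    def basin_fractions(self) -> np.ndarray:
        """p_rho = basin size / 2^N per attractor; sums to 1."""
        total = 1 << self.N
        return np.array(
            [self.basin_sizes[a.canonical_key] / total for a in self.attractors]
        )


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def find_attractors(net: BooleanNetwork, cap: int = DEFAULT_NODE_CAP) -> StateSpaceAnalysis:
    """Exhaustively assign all 2^N states to attractors.

    Iterative successor tracing with memoized state->attractor coloring:
    linear in the state-space size. Raises :class:`SizeLimitError` when
    ``net.N > cap``.
    """
    n = net.N
    if n > cap:
        raise SizeLimitError(
            f"exhaustive analysis limited to N <= {cap} nodes (got N={n})"
        )
    succ = transition_table(net)
    size = 1 << n
    color = np.full(size, -1, dtype=np.int64)  # -1 unvisited, else attractor id
    attractors: list[Attractor] = []
    basin_counts: list[int] = []

    for start in range(size):
        if color[start] >= 0:
            continue
        path: list[int] = []
        on_path = {}
        x = start
        while color[x] < 0 and x not in on_path:
            on_path[x] = len(path)
            path.append(x)
            x = int(succ[x])
        if color[x] >= 0:
            aid = int(color[x])
        else:
            # new cycle discovered: path[on_path[x]:] is the attractor
            cycle = path[on_path[x]:]
            aid = len(attractors)
            attractors.append(Attractor(_canonical_cycle(cycle)))
            basin_counts.append(0)
        for s in path:
            color[s] = aid
        basin_counts[aid] += len(path)

    basin_sizes = {
        a.canonical_key: basin_counts[i] for i, a in enumerate(attractors)
    }
    return StateSpaceAnalysis(tuple(attractors), basin_sizes, n)


def attractor_count(analysis: StateSpaceAnalysis) -> int:
    return len(analysis.attractors)


def mean_attractor_length(analysis: StateSpaceAnalysis) -> float:
    return float(np.mean([a.length for a in analysis.attractors]))


def normalized_basin_entropy(analysis: StateSpaceAnalysis) -> float:
    """Basin entropy H = -sum p_rho log2 p_rho, normalized by node count N.

    Zero for a single attractor; 1 when every state is its own fixed point.
    """
    p = analysis.basin_fractions()
    p = p[p > 0]
    h = max(-np.sum(p * np.log2(p)), 0.0)  # avoid -0.0 for a single basin
    return float(h / analysis.N)
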