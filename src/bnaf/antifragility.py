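"""Fragility/antifragility of Boolean networks under transient state flips.

Complexity is measured on a late observation window of the dynamics:

* per node, ``E_i`` is the binary Shannon entropy of its 0/1 frequencies over
  the window; network emergence ``E`` is the mean of ``E_i``;
* self-organization ``S = 1 - E``; complexity ``C = 4 * E * (1 - E)``.

The perturbation protocol flips a fresh uniformly chosen subset of ``X``
nodes every ``O``-th step (flip first, then apply the synchronous update),
runs ``2 T`` steps, and observes the ``T`` post-update states at
``t = T + 1 .. 2 T`` so transients are largely excluded. With perturbation
degree ``dx = X / (N * O)`` and satisfaction change ``ds = C - C0``
(perturbed-minus-unperturbed mean complexity over ``s`` shared initial
states), the fragility value is ``-ds * dx``: negative means antifragile
(complexity gained under perturbation), zero robust, positive fragile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .errors import IncomparableError
from .network_core import BooleanNetwork, step_states
from .rngutil import substream

__all__ = [
    "PerturbationConfig",
    "ComplexityMeasurement",
    "FragilityPoint",
    "FragilityCurve",
    "DifferenceCurve",
    "emergence",
    "complexity",
    "delta_x",
    "perturbed_window",
    "fragility",
    "fragility_curve",
    "difference_curve",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Protocol parameters: window length T, period O, initial-state count s.

    ``X_values`` defaults to 1..N of the analyzed network when left None.
    """

    T: int = 200
    O: int = 1
    s: int = 1000
    seed: int = 0
    X_values: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.T < 1 or self.O < 1 or self.s < 1:
            raise ValueError("require T >= 1, O >= 1, s >= 1")


@dataclass(frozen=True)
class ComplexityMeasurement:
    p0: np.ndarray
    p1: np.ndarray
    E_i: np.ndarray
    E: float
    S: float
    C: float


@dataclass(frozen=True)
class FragilityPoint:
    X: int
    delta_x: float
    C0: float
    C: float

    @property
    def delta_sigma(self) -> float:
        return self.C - self.C0

    @property
    def fragility(self) -> float:
        return -self.delta_sigma * self.delta_x


@dataclass(frozen=True)
class FragilityCurve:
    """Fragility values over increasing perturbed-node counts X for one network."""

    points: tuple[FragilityPoint, ...]
    N: int

    def __post_init__(self):
        xs = [p.X for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("X values must be strictly increasing")

    @property
    def X(self) -> np.ndarray:
        return np.array([p.X for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.fragility for p in self.points])


@dataclass(frozen=True)
class DifferenceCurve:
    """Original-minus-mutant fragility, interpolated onto a fixed-length grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.grid) != len(self.values):
            raise ValueError("grid/values length mismatch")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    # xlogy handles the 0*log(0) = 0 convention
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / np.log(2.0)


def emergence(window, n: int | None = None) -> ComplexityMeasurement:
    """Complexity measurement from an observation window of states.

    ``window`` is either a 2-D 0/1 array (rows = time, columns = nodes) or a
    sequence of integer-encoded states, in which case ``n`` (node count) is
    required.
    """
    arr = np.asarray(window)
    if arr.ndim == 1:
        if n is None:
            raise ValueError("n (node count) required for integer-encoded windows")
        arr = (arr[:, None] >> np.arange(n)) & 1
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("window must be a nonempty sequence of states")
    p1 = arr.mean(axis=0)
    p0 = 1.0 - p1
    e_i = _binary_entropy(p1)
    e = float(e_i.mean())
    return ComplexityMeasurement(p0, p1, e_i, e, 1.0 - e, complexity(e))


def complexity(E: float) -> float:
    """C = 4 E (1 - E): zero at both entropy extremes, maximal (1) at E = 0.5."""
    if not 0.0 <= E <= 1.0:
        raise ValueError(f"E must lie in [0, 1], got {E}")
    return 4.0 * E * (1.0 - E)


def delta_x(X: int, N: int, O: int) -> float:
    """Perturbation degree X / (N * O), in [0, 1]."""
    if not 0 <= X <= N:
        raise ValueError(f"require 0 <= X <= N, got X={X}, N={N}")
    if O < 1:
        raise ValueError("O must be >= 1")
    return X / (N * O)


def _flip_masks(s: int, n: int, x: int, rng: np.random.Generator) -> np.ndarray:
    """One XOR mask per run flipping a fresh uniform X-subset of nodes."""
    if x == n:
        return np.full(s, (1 << n) - 1, dtype=np.int64)
    scores = rng.random((s, n))
    chosen = np.argpartition(scores, x - 1, axis=1)[:, :x].astype(np.int64)
    return np.bitwise_or.reduce(np.int64(1) << chosen, axis=1)


def _run_complexities(
    net: BooleanNetwork,
    initials: np.ndarray,
    X: int,
    T: int,
    O: int,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Per-run complexity C over the T+1..2T window, vectorized over runs."""
    n = net.N
    s = len(initials)
    states = initials.astype(np.int64).copy()
    counts = np.zeros((s, n), dtype=np.int64)
    node_shifts = np.arange(n)
    for step in range(2 * T):
        if X > 0 and step % O == 0:
            states ^= _flip_masks(s, n, X, rng)
        states = step_states(net, states)
        if step >= T:
            counts += (states[:, None] >> node_shifts) & 1
    p1 = counts / T
    e = _binary_entropy(p1).mean(axis=1)
    return 4.0 * e * (1.0 - e)


def sample_initial_states(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """s distinct initial states; the whole state space when 2^N <= s."""
    size = 1 << n
    if size <= s:
        return np.arange(size, dtype=np.int64)
    if size <= 1 << 20:
        return rng.choice(size, size=s, replace=False).astype(np.int64)
    # rejection sampling avoids materializing 2^N entries
    picked: set[int] = set()
    while len(picked) < s:
        draw = rng.integers(size, size=s - len(picked))
        picked.update(int(v) for v in draw)
    return np.fromiter(picked, dtype=np.int64, count=s)


def perturbed_window(
    net: BooleanNetwork,
    initial: int,
    X: int,
    T: int,
    O: int,
    rng: np.random.Generator,
) -> list[int]:
    """The T post-update states at t = T+1 .. 2T for one perturbed run.

    At every step index divisible by O a fresh uniform X-subset of nodes is
    flipped in the current state, then the synchronous update is applied.
    """
    if not 0 <= X <= net.N:
        raise ValueError("require 0 <= X <= N")
    x = np.array([initial], dtype=np.int64)
    out: list[int] = []
    for step in range(2 * T):
        if X > 0 and step % O == 0:
            x ^= _flip_masks(1, net.N, X, rng)
        x = step_states(net, x)
        if step >= T:
            out.append(int(x[0]))
    return out


def fragility(
    net: BooleanNetwork,
    X: int,
    config: PerturbationConfig,
    _initials: np.ndarray | None = None,
    _C0: float | None = None,
) -> FragilityPoint:
    """Fragility at one perturbation size X, averaged over s shared initial states.

    The unperturbed (C0) and perturbed (C) complexities use the same initial
    states; the per-X perturbation stream depends only on (seed, X), so a
    mutant analyzed under the same config sees identical random draws
    (common-random-numbers variance reduction).
    """
    if not 0 <= X <= net.N:
        raise ValueError("require 0 <= X <= N")
    if _initials is None:
        _initials = sample_initial_states(
            net.N, config.s, substream(config.seed, "initials")
        )
    if _C0 is None:
        _C0 = float(
            _run_complexities(net, _initials, 0, config.T, config.O, None).mean()
        )
    if X == 0:
        c = _C0
    else:
        rng = substream(config.seed, "perturb", X)
        c = float(_run_complexities(net, _initials, X, config.T, config.O, rng).mean())
    return FragilityPoint(X, delta_x(X, net.N, config.O), _C0, c)


def fragility_curve(net: BooleanNetwork, config: PerturbationConfig) -> FragilityCurve:
    """One FragilityPoint per X (default X = 1..N), sharing initial states and C0."""
    xs = config.X_values if config.X_values is not None else tuple(range(1, net.N + 1))
    if any(not 0 <= x <= net.N for x in xs):
        raise ValueError("every X must lie in [0, N]")
    initials = sample_initial_states(net.N, config.s, substream(config.seed, "initials"))
    c0 = float(_run_complexities(net, initials, 0, config.T, config.O, None).mean())
    points = tuple(
        fragility(net, x, config, _initials=initials, _C0=c0) for x in xs
    )
    return FragilityCurve(points, net.N)


def difference_curve(
    original: FragilityCurve, mutated: FragilityCurve, points: int = 30
) -> DifferenceCurve:
    """Original-minus-mutant fragility on ``points`` normalized abscissae.

    Both curves are piecewise-linearly interpolated on the normalized axis
    X/N over ``points`` evenly spaced targets spanning [1/N, 1], making
    networks of different size comparable at a fixed feature width.
    """
    if original.N != mutated.N:
        raise IncomparableError(
            f"curves computed over N={original.N} and N={mutated.N}"
        )
    if not np.array_equal(original.X, mutated.X):
        raise IncomparableError("curves computed on different X grids")
    n = original.N
    grid = np.linspace(1.0 / n, 1.0, points)
    native = original.X / n
    orig = np.interp(grid, native, original.values)
    mut = np.interp(grid, native, mutated.values)
    return DifferenceCurve(grid, orig - mut)
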