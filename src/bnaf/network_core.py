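"""Synchronous Boolean networks: representation, dynamics, random generation, I/O.

Conventions
-----------
States are integers in ``[0, 2**N)``; node index 0 is the *least* significant
bit. Within one node's truth table the *first* listed input is the *most*
significant bit of the row index, i.e. for inputs ``(a, b)`` row
``r = (bit(a) << 1) | bit(b)``.

Networks are immutable value objects; all dynamics operations are pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidStateError, NetworkParseError

__all__ = [
    "BooleanNetwork",
    "RBNConfig",
    "state_from_string",
    "state_to_string",
    "synchronous_step",
    "step_states",
    "trajectory",
    "transition_table",
    "generate_rbn",
    "network_from_state_map",
    "read_network",
    "write_network",
]


# ---------------------------------------------------------------------------
# state helpers


def state_from_string(s: str) -> int:
    """Parse a bitstring ``"v1v2...vN"`` (node 0 first) into an integer state."""
    if not s or any(c not in "01" for c in s):
        raise InvalidStateError(f"not a bitstring: {s!r}")
    return sum(int(c) << i for i, c in enumerate(s))


def state_to_string(x: int, n: int) -> str:
    """Format an integer state as a bitstring with node 0 in the first position."""
    return "".join(str((x >> i) & 1) for i in range(n))


def _as_state(state: int | Sequence[int] | str, n: int) -> int:
    """Normalize a state given as int, bitstring, or bit sequence."""
    if isinstance(state, str):
        state = state_from_string(state)
        if state >= (1 << n):
            raise InvalidStateError("state wider than network")
        return state
    if isinstance(state, (int, np.integer)):
        if not 0 <= state < (1 << n):
            raise InvalidStateError(f"state {state} outside [0, 2^{n})")
        return int(state)
    bits = list(state)
    if len(bits) != n:
        raise InvalidStateError(f"state length {len(bits)} != N={n}")
    if any(b not in (0, 1) for b in bits):
        raise InvalidStateError("state entries must be 0/1")
    return sum(b << i for i, b in enumerate(bits))


# ---------------------------------------------------------------------------
# network type


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network G(V, F).

    Parameters
    ----------
    node_names
        Ordered node identifiers (defines node indices).
    inputs
        Per node, the ordered tuple of input node indices IN(v_i). Self-inputs
        are allowed; duplicates are not. A node may have zero inputs, in which
        case its truth table is the 1-entry constant.
    truth_tables
        Per node, a tuple of 0/1 ints of length ``2**k_i`` giving the update
        function on every input row.
    """

    node_names: tuple[str, ...]
    inputs: tuple[tuple[int, ...], ...]
    truth_tables: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        n = len(self.node_names)
        object.__setattr__(self, "node_names", tuple(self.node_names))
        object.__setattr__(self, "inputs", tuple(tuple(t) for t in self.inputs))
        object.__setattr__(
            self, "truth_tables", tuple(tuple(int(b) for b in t) for t in self.truth_tables)
        )
        if n < 1:
            raise ValueError("network needs at least one node")
        if len(self.inputs) != n or len(self.truth_tables) != n:
            raise ValueError("inputs/truth_tables length must equal node count")
        for i, (ins, tab) in enumerate(zip(self.inputs, self.truth_tables)):
            if len(set(ins)) != len(ins):
                raise ValueError(f"node {i}: duplicated input index")
            if any(not 0 <= j < n for j in ins):
                raise ValueError(f"node {i}: input index out of range")
            if len(tab) != 1 << len(ins):
                raise ValueError(
                    f"node {i}: table length {len(tab)} != 2^{len(ins)}"
                )
            if any(b not in (0, 1) for b in tab):
                raise ValueError(f"node {i}: table entries must be 0/1")

    @property
    def N(self) -> int:
        return len(self.node_names)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Directed edge set E = {(source, target)} induced by the input lists."""
        return {(src, i) for i, ins in enumerate(self.inputs) for src in ins}

    def canonical_encoding(self) -> tuple:
        """Hashable encoding of (inputs, truth_tables); equal iff same wiring+logic."""
        return (self.inputs, self.truth_tables)


@dataclass(frozen=True)
class RBNConfig:
    """Parameters of a Kauffman N-K random Boolean network."""

    N: int
    K: int
    seed: int
    bias: float = 0.5

    def __post_init__(self):
        if not 1 <= self.K <= self.N:
            raise ValueError(f"require 1 <= K <= N, got K={self.K}, N={self.N}")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")


# ---------------------------------------------------------------------------
# dynamics


def _row_indices(net: BooleanNetwork, states: np.ndarray, node: int) -> np.ndarray:
    r = np.zeros(states.shape, dtype=np.int64)
    for inp in net.inputs[node]:
        r = (r << 1) | ((states >> inp) & 1)
    return r


def step_states(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Vectorized synchronous update of an integer-encoded state array."""
    states = np.asarray(states, dtype=np.int64)
    out = np.zeros(states.shape, dtype=np.int64)
    for i in range(net.N):
        tab = np.asarray(net.truth_tables[i], dtype=np.int64)
        out |= tab[_row_indices(net, states, i)] << i
    return out


def synchronous_step(net: BooleanNetwork, state: int | Sequence[int] | str) -> int:
    """One synchronous update v(t+1) = f(v(t))."""
    x = _as_state(state, net.N)
    return int(step_states(net, np.array([x]))[0])


def trajectory(
    net: BooleanNetwork, initial: int | Sequence[int] | str, steps: int
) -> list[int]:
    """States v(0..steps) under synchronous update (length ``steps + 1``)."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    x = _as_state(initial, net.N)
    out = [x]
    for _ in range(steps):
        x = synchronous_step(net, x)
        out.append(x)
    return out


def transition_table(net: BooleanNetwork) -> np.ndarray:
    """Successor of every state: array ``t`` with ``t[x] = f(x)`` for all 2^N states."""
    size = 1 << net.N
    return step_states(net, np.arange(size, dtype=np.int64))


# ---------------------------------------------------------------------------
# generation


def generate_rbn(config: RBNConfig) -> BooleanNetwork:
    """Generate a Kauffman N-K random Boolean network.

    Each node receives exactly K distinct inputs drawn uniformly from all N
    nodes (self-inputs allowed) and a truth table of i.i.d. Bernoulli(bias)
    bits. Identical config (including seed) yields an identical network.
    """
    rng = np.random.default_rng(config.seed)
    names = tuple(f"v{i}" for i in range(config.N))
    inputs = []
    tables = []
    for _ in range(config.N):
        ins = rng.choice(config.N, size=config.K, replace=False)
        inputs.append(tuple(int(j) for j in ins))
        bits = rng.random(1 << config.K) < config.bias
        tables.append(tuple(int(b) for b in bits))
    return BooleanNetwork(names, tuple(inputs), tuple(tables))


def network_from_state_map(
    state_map: dict[int, int], n: int, node_names: Sequence[str] | None = None
) -> BooleanNetwork:
    """Build an N-node network realizing an explicit successor map on all 2^N states.

    Every node takes all N nodes as inputs, listed as (0, 1, ..., N-1), so
    node 0 occupies the most significant row-index bit. Useful for building
    fixture networks with a prescribed state-transition diagram.
    """
    size = 1 << n
    if sorted(state_map) != list(range(size)):
        raise ValueError("state_map must cover every state exactly once")
    names = tuple(node_names) if node_names else tuple(f"v{i}" for i in range(n))
    ins = tuple(range(n))
    tables = []
    for i in range(n):
        tab = []
        for row in range(size):
            # row bits: first input (node 0) is most significant
            state = sum(((row >> (n - 1 - j)) & 1) << j for j in range(n))
            tab.append((state_map[state] >> i) & 1)
        tables.append(tuple(tab))
    return BooleanNetwork(names, tuple(ins for _ in range(n)), tuple(tables))


# ---------------------------------------------------------------------------
# rule expressions

_TOKEN_CHARS = set("&|!()")


def _tokenize(expr: str, line: int | None) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
        elif c in _TOKEN_CHARS:
            tokens.append(c)
            i += 1
        elif c.isalnum() or c == "_":
            j = i
            while j < len(expr) and (expr[j].isalnum() or expr[j] in "_."):
                j += 1
            tokens.append(expr[i:j])
            i = j
        else:
            raise NetworkParseError(f"unexpected character {c!r} in rule", line)
    return tokens


class _ExprParser:
    """Recursive-descent parser for AND/OR/NOT/parenthesis/constant rules."""

    def __init__(self, tokens: list[str], line: int | None):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise NetworkParseError("unexpected end of rule", self.line)
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise NetworkParseError(f"trailing token {self.peek()!r}", self.line)
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise NetworkParseError("expected ')'", self.line)
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in _TOKEN_CHARS:
            raise NetworkParseError(f"unexpected token {tok!r}", self.line)
        return ("var", tok)


def _expr_vars(node, acc: list[str]):
    kind = node[0]
    if kind == "var" and node[1] not in acc:
        acc.append(node[1])
    elif kind in ("and", "or"):
        _expr_vars(node[1], acc)
        _expr_vars(node[2], acc)
    elif kind == "not":
        _expr_vars(node[1], acc)


def _eval_expr(node, env: dict[str, int]) -> int:
    kind = node[0]
    if kind == "const":
        return node[1]
    if kind == "var":
        return env[node[1]]
    if kind == "not":
        return 1 - _eval_expr(node[1], env)
    a = _eval_expr(node[1], env)
    b = _eval_expr(node[2], env)
    return a & b if kind == "and" else a | b


def compile_rule(expr: str, line: int | None = None) -> tuple[list[str], list[int]]:
    """Compile a rule expression to (ordered input names, truth table).

    Input order is first appearance in the expression; the first input is the
    most significant row-index bit. Returns a 1-entry constant table for
    variable-free expressions.
    """
    ast = _ExprParser(_tokenize(expr, line), line).parse()
    variables: list[str] = []
    _expr_vars(ast, variables)
    k = len(variables)
    table = []
    for row in range(1 << k):
        env = {v: (row >> (k - 1 - j)) & 1 for j, v in enumerate(variables)}
        table.append(_eval_expr(ast, env))
    return variables, table


# ---------------------------------------------------------------------------
# file I/O


def _format_expression(net: BooleanNetwork, node: int) -> str:
    """Disjunctive normal form of a node's truth table over its input names."""
    ins = net.inputs[node]
    tab = net.truth_tables[node]
    k = len(ins)
    if k == 0:
        return str(tab[0])
    if all(b == 1 for b in tab):
        return "1"
    if all(b == 0 for b in tab):
        return "0"
    minterms = []
    for row, bit in enumerate(tab):
        if not bit:
            continue
        lits = []
        for j, src in enumerate(ins):
            name = net.node_names[src]
            lits.append(name if (row >> (k - 1 - j)) & 1 else f"!{name}")
        minterms.append("(" + " & ".join(lits) + ")")
    return " | ".join(minterms)


def write_network(net: BooleanNetwork, path, format: str = "bnet") -> None:
    """Write a network as text.

    ``bnet``: one ``name, expression`` line per node (header ``targets, factors``).
    ``table``: exact dialect ``name, inputs=a;b;c, table=0110...`` preserving
    input order and raw tables bit-for-bit.
    """
    lines = []
    if format == "bnet":
        lines.append("targets, factors")
        for i in range(net.N):
            lines.append(f"{net.node_names[i]}, {_format_expression(net, i)}")
    elif format == "table":
        for i in range(net.N):
            names = ";".join(net.node_names[j] for j in net.inputs[i])
            bits = "".join(str(b) for b in net.truth_tables[i])
            lines.append(f"{net.node_names[i]}, inputs={names}, table={bits}")
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_network(path, format: str | None = None) -> BooleanNetwork:
    """Read a network from a text file (dialect auto-detected per line).

    Raises :class:`NetworkParseError` (with line number) for malformed rules
    or references to undeclared nodes.
    """
    with open(path) as fh:
        raw = fh.readlines()
    entries: list[tuple[int, str, str]] = []  # (lineno, name, remainder)
    for lineno, line in enumerate(raw, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if stripped.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in stripped:
            raise NetworkParseError("expected 'name, rule'", lineno)
        name, rest = stripped.split(",", 1)
        name = name.strip()
        if not name:
            raise NetworkParseError("empty node name", lineno)
        entries.append((lineno, name, rest.strip()))
    if not entries:
        raise NetworkParseError("no node definitions found")
    names = [name for _, name, _ in entries]
    if len(set(names)) != len(names):
        raise NetworkParseError("duplicated node definition")
    index = {name: i for i, name in enumerate(names)}

    inputs: list[tuple[int, ...]] = []
    tables: list[tuple[int, ...]] = []
    for lineno, name, rest in entries:
        if rest.startswith("inputs="):
            parts = [p.strip() for p in rest.split(",")]
            if len(parts) != 2 or not parts[1].startswith("table="):
                raise NetworkParseError("expected 'inputs=..., table=...'", lineno)
            in_names = [p for p in parts[0][len("inputs="):].split(";") if p]
            bits = parts[1][len("table="):]
            for nm in in_names:
                if nm not in index:
                    raise NetworkParseError(f"undeclared node {nm!r}", lineno)
            if len(set(in_names)) != len(in_names):
                raise NetworkParseError("duplicated input", lineno)
            if len(bits) != 1 << len(in_names) or any(c not in "01" for c in bits):
                raise NetworkParseError("bad table bitstring", lineno)
            inputs.append(tuple(index[nm] for nm in in_names))
            tables.append(tuple(int(c) for c in bits))
        else:
            in_names, table = compile_rule(rest, lineno)
            for nm in in_names:
                if nm not in index:
                    raise NetworkParseError(f"undeclared node {nm!r}", lineno)
            inputs.append(tuple(index[nm] for nm in in_names))
            tables.append(tuple(table))
    return BooleanNetwork(tuple(names), tuple(inputs), tuple(tables))
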