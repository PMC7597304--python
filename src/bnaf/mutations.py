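"""Elementary internal perturbations of Boolean networks.

Four mutation kinds, each a single structural edit that preserves the node
set: add one regulatory link, delete one, re-point one (``change``), or flip
one output bit of a truth table.

Truth-table adjustment conventions (the add/delete kinds must reshape the
target node's table):

* ``add``: the new input is inserted in the *first* (most significant
  row-index) position, so rows with the new input at 0 are the original table
  verbatim and rows with the new input at 1 are filled with seeded random
  bits. Hence deleting the just-added link restores the network exactly.
* ``delete``: the sub-table where the deleted input equals 0 is kept.
* ``change``: one incoming edge is re-pointed to a new source; the table is
  untouched (same arity, new wiring).

Self-links are allowed everywhere; parallel edges never are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExhaustionError, MutationError
from .network_core import BooleanNetwork

__all__ = ["Mutation", "MUTATION_KINDS", "apply_mutation", "sample_mutants"]

MUTATION_KINDS = ("add", "delete", "change", "flip")


@dataclass(frozen=True)
class Mutation:
    """One elementary perturbation.

    Field usage by kind:
      add    -- target_node, source_node (new input), fill_seed (new table rows)
      delete -- target_node, source_node (input removed)
      change -- target_node, source_node (existing input), new_source
      flip   -- target_node, table_row
    """

    kind: str
    target_node: int
    source_node: int | None = None
    new_source: int | None = None
    table_row: int | None = None
    fill_seed: int | None = None

    def __post_init__(self):
        if self.kind not in MUTATION_KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


def _replace_node(
    net: BooleanNetwork, node: int, inputs: tuple[int, ...], table: tuple[int, ...]
) -> BooleanNetwork:
    new_inputs = list(net.inputs)
    new_tables = list(net.truth_tables)
    new_inputs[node] = inputs
    new_tables[node] = table
    return BooleanNetwork(net.node_names, tuple(new_inputs), tuple(new_tables))


def apply_mutation(net: BooleanNetwork, m: Mutation) -> BooleanNetwork:
    """Return a new network with the mutation applied; ``net`` is not modified."""
    t = m.target_node
    if not 0 <= t < net.N:
        raise MutationError(f"target node {t} out of range")
    ins = net.inputs[t]
    tab = net.truth_tables[t]
    k = len(ins)

    if m.kind == "add":
        if m.source_node is None or m.fill_seed is None:
            raise MutationError("add requires source_node and fill_seed")
        if m.source_node in ins:
            raise MutationError(
                f"add: node {m.source_node} is already an input of {t}"
            )
        if not 0 <= m.source_node < net.N:
            raise MutationError("add: source out of range")
        fill = np.random.default_rng(m.fill_seed).integers(0, 2, size=len(tab))
        new_table = tuple(tab) + tuple(int(b) for b in fill)
        return _replace_node(net, t, (m.source_node,) + ins, new_table)

    if m.kind == "delete":
        if m.source_node is None:
            raise MutationError("delete requires source_node")
        if m.source_node not in ins:
            raise MutationError(f"delete: node {m.source_node} is not an input of {t}")
        pos = ins.index(m.source_node)
        rows = np.arange(len(tab))
        keep = ((rows >> (k - 1 - pos)) & 1) == 0
        new_table = tuple(np.asarray(tab)[keep].tolist())
        new_inputs = ins[:pos] + ins[pos + 1:]
        return _replace_node(net, t, new_inputs, new_table)

    if m.kind == "change":
        if m.source_node is None or m.new_source is None:
            raise MutationError("change requires source_node and new_source")
        if m.source_node not in ins:
            raise MutationError(f"change: node {m.source_node} is not an input of {t}")
        if m.new_source in ins:
            raise MutationError(
                f"change: node {m.new_source} is already an input of {t}"
            )
        if not 0 <= m.new_source < net.N:
            raise MutationError("change: new source out of range")
        pos = ins.index(m.source_node)
        new_inputs = ins[:pos] + (m.new_source,) + ins[pos + 1:]
        return _replace_node(net, t, new_inputs, tab)

    # flip
    if m.table_row is None:
        raise MutationError("flip requires table_row")
    if not 0 <= m.table_row < len(tab):
        raise MutationError(f"flip: row {m.table_row} >= table length {len(tab)}")
    new_table = list(tab)
    new_table[m.table_row] = 1 - new_table[m.table_row]
    return _replace_node(net, t, ins, tuple(new_table))


def _draw_mutation(net: BooleanNetwork, kind: str, rng: np.random.Generator) -> Mutation | None:
    """Draw one random mutation of the given kind, or None if inapplicable."""
    n = net.N
    if kind == "add":
        candidates = [i for i in range(n) if len(net.inputs[i]) < n]
        if not candidates:
            return None
        t = int(rng.choice(candidates))
        free = [j for j in range(n) if j not in net.inputs[t]]
        src = int(rng.choice(free))
        return Mutation("add", t, source_node=src, fill_seed=int(rng.integers(2**63)))
    if kind == "delete":
        candidates = [i for i in range(n) if len(net.inputs[i]) >= 1]
        if not candidates:
            return None
        t = int(rng.choice(candidates))
        src = int(rng.choice(net.inputs[t]))
        return Mutation("delete", t, source_node=src)
    if kind == "change":
        candidates = [i for i in range(n) if 1 <= len(net.inputs[i]) < n]
        if not candidates:
            return None
        t = int(rng.choice(candidates))
        src = int(rng.choice(net.inputs[t]))
        free = [j for j in range(n) if j not in net.inputs[t]]
        new = int(rng.choice(free))
        return Mutation("change", t, source_node=src, new_source=new)
    # flip
    t = int(rng.integers(n))
    row = int(rng.integers(len(net.truth_tables[t])))
    return Mutation("flip", t, table_row=row)


def sample_mutants(
    net: BooleanNetwork, n: int, seed: int, max_attempts_per_mutant: int = 200
) -> list[tuple[Mutation, BooleanNetwork]]:
    """Sample ``n`` pairwise-distinct single-edit mutants of ``net``.

    The four kinds are distributed as equally as possible (per-kind counts
    differ by at most 1); if a kind is inapplicable or exhausted, its quota is
    redistributed to the other kinds. Distinctness is judged on the mutated
    network's canonical (inputs, tables) encoding, so two different mutation
    descriptions yielding the same network count once. Deterministic for a
    fixed (net, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    quotas = {k: n // 4 for k in MUTATION_KINDS}
    for k in rng.permutation(MUTATION_KINDS)[: n % 4]:
        quotas[str(k)] += 1

    seen: set[tuple] = {net.canonical_encoding()}
    cohort: list[tuple[Mutation, BooleanNetwork]] = []

    def fill(kind: str, want: int) -> int:
        got = 0
        failures = 0
        budget = max_attempts_per_mutant * max(want, 1)
        while got < want and failures < budget:
            m = _draw_mutation(net, kind, rng)
            if m is None:
                break
            mutant = apply_mutation(net, m)
            enc = mutant.canonical_encoding()
            if enc in seen:
                failures += 1
                continue
            seen.add(enc)
            cohort.append((m, mutant))
            got += 1
        return got

    leftover = 0
    for kind in MUTATION_KINDS:
        leftover += quotas[kind] - fill(kind, quotas[kind])
    # redistribute unmet quota across the other kinds (round-robin)
    rounds = 0
    while leftover > 0 and rounds < 4:
        for kind in MUTATION_KINDS:
            if leftover == 0:
                break
            leftover -= fill(kind, leftover)
        rounds += 1
    if leftover > 0:
        raise ExhaustionError(
            f"could only sample {len(cohort)} distinct mutants out of {n} requested"
        )
    return cohort
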