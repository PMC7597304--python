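"""Four-class robustness/evolvability labels from attractor-set comparison.

A mutant is *robust* when every original attractor survives, and *evolvable*
when it exhibits at least one attractor the original lacks. Attractors are
compared as state sets over the same node count, so cycle rotation is
irrelevant and no tolerance is involved.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import chi2_contingency

from .attractor_analysis import StateSpaceAnalysis, find_attractors
from .errors import IncomparableError
from .mutations import Mutation
from .network_core import BooleanNetwork

__all__ = [
    "RobustnessClass",
    "ClassDistribution",
    "classify_change",
    "classify_mutant",
    "class_distribution",
    "cramers_v",
]


class RobustnessClass(enum.Enum):
    NOT_ROBUST_NOT_EVOLVABLE = "not_robust_not_evolvable"
    NOT_ROBUST_EVOLVABLE = "not_robust_evolvable"
    ROBUST_NOT_EVOLVABLE = "robust_not_evolvable"
    ROBUST_EVOLVABLE = "robust_evolvable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: fixed label order used for contingency tables and classifier outputs
CLASS_ORDER = tuple(RobustnessClass)


@dataclass(frozen=True)
class ClassDistribution:
    """Percentage frequency of the four classes over one mutant cohort."""

    percentages: dict[RobustnessClass, float]
    n_mutants: int

    def __post_init__(self):
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, expected 100")


def classify_change(
    A: Iterable[frozenset[int]] | StateSpaceAnalysis,
    A_prime: Iterable[frozenset[int]] | StateSpaceAnalysis,
) -> RobustnessClass:
    """Classify a mutation by comparing original (A) and mutant (A') attractor sets.

    A' = A  -> robust & not evolvable;  A' a strict superset -> robust &
    evolvable;  A' a strict subset -> not robust & not evolvable; otherwise
    (each side holds an attractor the other lacks) -> not robust & evolvable.
    """
    if isinstance(A, StateSpaceAnalysis) and isinstance(A_prime, StateSpaceAnalysis):
        if A.N != A_prime.N:
            raise IncomparableError(
                f"cannot compare attractors over N={A.N} and N={A_prime.N}"
            )
    a = frozenset(A.attractor_keys if isinstance(A, StateSpaceAnalysis) else map(frozenset, A))
    b = frozenset(
        A_prime.attractor_keys
        if isinstance(A_prime, StateSpaceAnalysis)
        else map(frozenset, A_prime)
    )
    if not a or not b:
        raise ValueError("attractor sets must be nonempty")
    if a == b:
        return RobustnessClass.ROBUST_NOT_EVOLVABLE
    if a < b:
        return RobustnessClass.ROBUST_EVOLVABLE
    if b < a:
        return RobustnessClass.NOT_ROBUST_NOT_EVOLVABLE
    return RobustnessClass.NOT_ROBUST_EVOLVABLE


def classify_mutant(
    net: BooleanNetwork, mutant: BooleanNetwork, cap: int = 26
) -> RobustnessClass:
    """Convenience wrapper: enumerate both attractor sets and classify."""
    return classify_change(find_attractors(net, cap), find_attractors(mutant, cap))


def class_distribution(
    net: BooleanNetwork,
    mutants: list[tuple[Mutation, BooleanNetwork]] | list[BooleanNetwork],
    cap: int = 26,
) -> ClassDistribution:
    """Percentage frequency distribution of the four classes over a cohort."""
    if not mutants:
        raise ValueError("empty mutant cohort")
    original = find_attractors(net, cap)
    counts = {c: 0 for c in CLASS_ORDER}
    for item in mutants:
        mutant = item[1] if isinstance(item, tuple) else item
        counts[classify_change(original, find_attractors(mutant, cap))] += 1
    n = len(mutants)
    return ClassDistribution({c: 100.0 * counts[c] / n for c in CLASS_ORDER}, n)


def cramers_v(table) -> float:
    """Cramer's V association strength for a contingency table of counts.

    V = sqrt(chi2 / (n * min(r - 1, c - 1))) with the plain Pearson
    chi-square statistic (no continuity correction); V lies in [0, 1].
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("counts must be nonnegative integers")
    n = t.sum()
    if n <= 0:
        raise ValueError("contingency table must have a positive total")
    # degenerate margins (all-zero row/column) carry no association information
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table degenerates to fewer than 2 rows/columns")
    chi2 = chi2_contingency(t, correction=False)[0]
    v = np.sqrt(chi2 / (n * (min(t.shape) - 1)))
    return float(min(v, 1.0))
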