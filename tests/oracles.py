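"""Independent oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, exact
rational arithmetic, plain loops) that share no code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def enum_overlap_distribution(n_universe: int, n_a: int, n_b: int) -> dict[int, int]:
    """Count, over ALL C(N, n_b) draws of set B, how many draws give each
    overlap size with the fixed set A = {0..n_a-1}. Exhaustive enumeration."""
    a = set(range(n_a))
    counts: dict[int, int] = {}
    for draw in combinations(range(n_universe), n_b):
        k = len(a.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
    return counts


def enum_tail(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> Fraction:
    """P(X >= n_overlap) by exhaustive draw enumeration (exact rational)."""
    counts = enum_overlap_distribution(n_universe, n_a, n_b)
    hits = sum(c for k, c in counts.items() if k >= n_overlap)
    return Fraction(hits, comb(n_universe, n_b))


def comb_tail(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> Fraction:
    """One-sided Fisher p by summing exact probabilities of all
    at-least-as-extreme 2x2 tables (exact rational arithmetic)."""
    total = comb(n_universe, n_b)
    acc = Fraction(0)
    for k in range(n_overlap, min(n_a, n_b) + 1):
        acc += Fraction(comb(n_a, k) * comb(n_universe - n_a, n_b - k), total)
    return acc


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up recipe, plain loops."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def vote_count(sets: list[set[str]], gene: str) -> int:
    return sum(1 for s in sets if gene in s)


def consensus_by_subset_enumeration(sets: list[set[str]], k: int) -> set[str]:
    """Genes lying in the intersection of at least one k-subset of the sets."""
    out: set[str] = set()
    n = len(sets)
    for size in range(k, n + 1):
        for idxs in combinations(range(n), size):
            inter = set.intersection(*(sets[i] for i in idxs))
            out |= inter
    return out


def venn_pattern_tally(sets: list[set[str]]) -> dict[tuple[int, ...], int]:
    """Region counts keyed by the sorted tuple of member set indices."""
    tally: dict[tuple[int, ...], int] = {}
    for gene in set().union(*sets):
        key = tuple(i for i, s in enumerate(sets) if gene in s)
        tally[key] = tally.get(key, 0) + 1
    return tally
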