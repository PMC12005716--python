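"""Independent oracles shared by the unit and acceptance suites.

Everything here recomputes expectations by brute force — enumeration,
exhaustive labelings, direct counting — never by calling the code path
under test.
"""
from __future__ import annotations

import itertools
from math import comb

from karyolg.formats_io import Phylogeny


def hypergeom_upper_tail(shared: int, total: int, n_a: int, n_b: int) -> float:
    """P[X >= shared] for X ~ Hypergeom(total, n_a, n_b), by enumeration."""
    denom = comb(total, n_b)
    num = 0
    for x in range(shared, min(n_a, n_b) + 1):
        if total - n_a >= n_b - x:
            num += comb(n_a, x) * comb(total - n_a, n_b - x)
    return num / denom


def brute_force_mbh(scores: dict[tuple[str, str], float]) -> set[tuple[str, str]]:
    """Mutual best hits by direct scanning of a dense (a, b) -> score map."""
    a_genes = {a for a, _ in scores}
    b_genes = {b for _, b in scores}
    best_a = {}
    for a in a_genes:
        row = {b: s for (x, b), s in scores.items() if x == a}
        top = max(row.values())
        winners = [b for b, s in row.items() if s == top]
        if len(winners) == 1:
            best_a[a] = winners[0]
    best_b = {}
    for b in b_genes:
        col = {a: s for (a, y), s in scores.items() if y == b}
        top = max(col.values())
        winners = [a for a, s in col.items() if s == top]
        if len(winners) == 1:
            best_b[b] = winners[0]
    return {(a, b) for a, b in best_a.items() if best_b.get(b) == a}


def brute_force_parsimony_cost(tree: Phylogeny, tip_states: dict[str, int]) -> int:
    """Minimum change count over all internal labelings (exhaustive)."""
    edges = tree.preorder_edges()
    internal = [n for n in tree.node_labels() if n not in tip_states]
    best = None
    for combo in itertools.product([0, 1], repeat=len(internal)):
        labels = dict(zip(internal, combo))
        labels.update(tip_states)
        cost = sum(1 for p, c, _ in edges if labels[p] != labels[c])
        best = cost if best is None else min(best, cost)
    return best


def labeling_cost(tree: Phylogeny, labels: dict[str, int]) -> int:
    return sum(1 for p, c, _ in tree.preorder_edges() if labels[p] != labels[c])


def exact_expected_het_adjacencies(labels: list) -> float:
    """E[# adjacent unequal-label pairs] over all permutations, by counting.

    Uses linearity of expectation over adjacent slots; exact for any
    label multiset.
    """
    n = len(labels)
    from collections import Counter

    counts = Counter(labels)
    same = sum(c * (c - 1) for c in counts.values()) / (n * (n - 1))
    return (n - 1) * (1 - same)
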