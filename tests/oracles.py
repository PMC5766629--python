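"""Independent brute-force oracles used by several test modules.

These deliberately avoid the code paths they check: betweenness by
explicit shortest-path enumeration, hypergeometric tails by exhaustive
combinatorics, the R-statistic by a literal two-pass transcription of
its formula, and BH by the literal step-up definition.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def betweenness_by_enumeration(g: nx.Graph) -> dict:
    """Normalized betweenness by enumerating every shortest path.

    For each unordered pair (s, t), all shortest s-t paths are listed
    and each interior node credited with its share; per-component
    normalization by 2/((N-1)(N-2)).
    """
    bc = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        for s, t in itertools.combinations(nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:  # pragma: no cover
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += share
        n = len(nodes)
        if n > 2:
            for v in nodes:
                bc[v] *= 2.0 / ((n - 1) * (n - 2))
        else:
            for v in nodes:
                bc[v] = 0.0
    return bc


def hypergeom_tail_by_enumeration(universe: frozenset, gene_set: frozenset,
                                  n_query: int, k: int) -> float:
    """P[overlap >= k] when a query of size n_query is drawn uniformly
    from the universe, by enumerating every possible draw."""
    hits = 0
    total = 0
    for draw in itertools.combinations(sorted(universe), n_query):
        total += 1
        if len(set(draw) & gene_set) >= k:
            hits += 1
    assert total == comb(len(universe), n_query)
    return hits / total


def r_score_two_pass(xi: np.ndarray, xj: np.ndarray, w: float = 0.5,
                     floor: float = 1e-5) -> np.ndarray:
    """Literal two-pass transcription of the R-statistic: explicit
    min/max, then the per-row formula."""
    inv = 1.0 / np.maximum(xj, floor)
    xi_min, xi_max = min(xi), max(xi)
    iv_min, iv_max = min(inv), max(inv)
    out = np.zeros(len(xi))
    for i in range(len(xi)):
        a = 0.0 if xi_max == xi_min else (xi[i] - xi_min) / (xi_max - xi_min)
        b = 0.0 if iv_max == iv_min else (inv[i] - iv_min) / (iv_max - iv_min)
        out[i] = w * a + (1 - w) * b
    return out


def bh_step_up(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition:
    q_(i) = min_{j >= i} min(1, m p_(j) / j) on the sorted p-values."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [min(1.0, m * p[order[i]] / (i + 1)) for i in range(m)]
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out
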