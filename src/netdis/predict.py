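"""Similarity-index link prediction on the observed network.

Two local indices are provided.  The common-neighbours (CN) score of a
candidate pair (x, y) is ``|Gamma(x) ∩ Gamma(y)|``; the resource-allocation
(RA) score down-weights hub intermediaries,
``sum over common neighbours z of 1/k_z``, modelling one unit of resource at
x split evenly among z's links.  RA is the default index for the
disintegration experiments; CN is the classical alternative.

Both indices are zero for pairs at graph distance greater than two, so only
distance-2 non-observed pairs are scored explicitly; all remaining candidate
pairs are treated as tied at score zero and enter selection only through the
uniform tie-break.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .graph import Edge, Node, canonical_edge

INDICES = ("ra", "cn")


def common_neighbors_score(g_o: nx.Graph, pair: tuple[Node, Node]) -> int:
    """Number of shared neighbours of the pair in the observed network."""
    x, y = pair
    if x not in g_o or y not in g_o:
        raise KeyError(f"pair {pair!r} not contained in the observed network")
    return len(set(g_o[x]) & set(g_o[y]))


def resource_allocation_score(g_o: nx.Graph, pair: tuple[Node, Node]) -> float:
    """Sum of reciprocal observed degrees over the pair's shared neighbours."""
    x, y = pair
    if x not in g_o or y not in g_o:
        raise KeyError(f"pair {pair!r} not contained in the observed network")
    return sum(1.0 / g_o.degree(z) for z in set(g_o[x]) & set(g_o[y]))


def score_candidates(g_o: nx.Graph, index: str = "ra") -> dict[Edge, float]:
    """Score every non-observed pair at distance two in G_O.

    Iterates neighbour pairs around each node, which visits exactly the
    pairs with at least one common neighbour; pairs absent from the result
    have score zero.
    """
    if index not in INDICES:
        raise ValueError(f"unknown index {index!r}; expected one of {INDICES}")
    scores: dict[Edge, float] = {}
    for z in g_o:
        neigh = list(g_o[z])
        if len(neigh) < 2:
            continue
        w = 1.0 / len(neigh) if index == "ra" else 1.0
        for x, y in combinations(neigh, 2):
            if g_o.has_edge(x, y):
                continue
            e = canonical_edge(x, y)
            scores[e] = scores.get(e, 0.0) + w
    return scores


def _zero_score_fill(
    g_o: nx.Graph,
    exclude: set[Edge],
    count: int,
    rng: np.random.Generator,
) -> list[Edge]:
    """Draw ``count`` distinct unobserved pairs outside ``exclude`` uniformly."""
    nodes = list(g_o.nodes())
    n = len(nodes)
    n_pairs = n * (n - 1) // 2
    observed = {canonical_edge(u, v) for u, v in g_o.edges()}
    n_available = n_pairs - len(observed) - len(exclude)
    if count > n_available:
        raise ValueError("requested more pairs than the candidate space holds")
    if n_pairs <= 200_000:
        pool = [
            e
            for e in (canonical_edge(u, v) for u, v in combinations(nodes, 2))
            if e not in observed and e not in exclude
        ]
        idx = rng.choice(len(pool), size=count, replace=False)
        return [pool[i] for i in idx]
    # large graphs: rejection sampling beats enumerating N(N-1)/2 pairs
    chosen: list[Edge] = []
    seen: set[Edge] = set()
    while len(chosen) < count:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = canonical_edge(nodes[i], nodes[j])
        if e in observed or e in exclude or e in seen:
            continue
        seen.add(e)
        chosen.append(e)
    return chosen


def rank_candidates(
    g_o: nx.Graph,
    scores: Mapping[Edge, float],
    n_needed: int,
    rng: np.random.Generator,
) -> list[Edge]:
    """The ``n_needed`` best candidate pairs, ties broken uniformly at random.

    Positive-score pairs are randomly permuted then stably sorted by
    descending score, so equal scores appear in seeded random order; if more
    pairs are needed than carry positive score, uniformly drawn zero-score
    candidates complete the list.  Selections at different sizes from the
    same ranking are nested, which the beta sweeps exploit.
    """
    items = list(scores.items())
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    items.sort(key=lambda kv: -kv[1])
    ranked = [e for e, _ in items[:n_needed]]
    if n_needed > len(items):
        ranked += _zero_score_fill(g_o, set(scores), n_needed - len(items), rng)
    return ranked


def select_predicted(
    g_o: nx.Graph,
    scores: Mapping[Edge, float],
    beta: float,
    rng: np.random.Generator,
) -> frozenset[Edge]:
    """Choose the top ``round(beta * |E_O|)`` candidate pairs as E_P.

    Round-half-to-even mirrors the missing-link convention.  ``beta`` may
    not request more pairs than the candidate space Omega_P contains; the
    admissible maximum is ``|Omega_P| / |E_O|``.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    n_obs = g_o.number_of_edges()
    n = g_o.number_of_nodes()
    n_space = n * (n - 1) // 2 - n_obs
    n_sel = round(beta * n_obs)
    if n_sel > n_space:
        beta_max = n_space / n_obs if n_obs else 0.0
        raise ValueError(
            f"beta={beta} requests {n_sel} links but the prediction space has "
            f"only {n_space}; admissible beta_max = {beta_max:.4g}"
        )
    return frozenset(rank_candidates(g_o, scores, n_sel, rng))


def improved_network(g_o: nx.Graph, e_p: Iterable[tuple[Node, Node]]) -> nx.Graph:
    """G_P: the observed network with the predicted links E_P added."""
    e_p_set = {canonical_edge(u, v) for u, v in e_p}
    overlap = [e for e in e_p_set if g_o.has_edge(*e)]
    if overlap:
        raise ValueError(f"predicted links already observed: {sorted(overlap)}")
    g_p = g_o.copy()
    g_p.add_edges_from(e_p_set)
    return g_p
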