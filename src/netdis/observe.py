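"""Missing-link observation model and prediction-quality metrics.

A fraction ``alpha`` of a network's links is hidden uniformly at random:
the attacker sees the observed network ``G_O = (V, E_O)`` (all nodes are
assumed known) and link prediction operates on the candidate space
``Omega_P`` of all unordered pairs not observed as links.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np

from .graph import Edge, Node, canonical_edge, canonical_edges


@dataclass(frozen=True)
class ObservationSplit:
    """Partition of a network's edges into observed and missing sets.

    ``alpha = |missing| / W`` is the missing-link fraction; the two sets are
    disjoint and their union is the full edge set of the source network.
    """

    observed: frozenset[Edge]
    missing: frozenset[Edge]
    alpha: float

    def __post_init__(self) -> None:
        if self.observed & self.missing:
            raise ValueError("observed and missing edge sets must be disjoint")


def observed_network(net: nx.Graph, split: ObservationSplit) -> nx.Graph:
    """The observed graph G_O: all nodes of ``net``, only observed edges."""
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(net.nodes())
    g.add_edges_from(split.observed)
    return g


def sample_missing_links(
    net: nx.Graph, alpha: float, rng: np.random.Generator
) -> ObservationSplit:
    """Hide a uniform random subset of ``round(alpha * W)`` links.

    Round-half-to-even fixes the missing count, so alpha is exact up to
    rounding.  No connectivity constraint is imposed on the remainder: the
    observed network may be disconnected or contain isolated nodes.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    edges = sorted(canonical_edge(u, v) for u, v in net.edges())
    w = len(edges)
    n_missing = round(alpha * w)
    idx = rng.choice(w, size=n_missing, replace=False) if n_missing else []
    missing = frozenset(edges[i] for i in idx)
    observed = frozenset(edges) - missing
    return ObservationSplit(observed=observed, missing=missing, alpha=alpha)


def candidate_space(
    split: ObservationSplit, net_nodes: Iterable[Node]
) -> frozenset[Edge]:
    """Prediction space Omega_P: all N(N-1)/2 pairs minus the observed links."""
    nodes = sorted(net_nodes, key=lambda x: (str(type(x)), x))
    all_pairs = frozenset(canonical_edge(u, v) for u, v in combinations(nodes, 2))
    return all_pairs - split.observed


def prediction_metrics(
    e_p: Iterable[tuple[Node, Node]], split: ObservationSplit
) -> tuple[float, float, frozenset[Edge]]:
    """Recall (R_TPR), precision (R_PPV) and the correctly predicted set E+.

    ``R_TPR = |E+| / |E_M|`` and ``R_PPV = |E+| / |E_P|`` with
    ``E+ = E_P ∩ E_M``; an empty denominator yields 0.  Predicting an
    already-observed link is a caller error.
    """
    e_p_set = canonical_edges(e_p)
    overlap = e_p_set & split.observed
    if overlap:
        raise ValueError(f"predicted links overlap observed links: {sorted(overlap)}")
    e_plus = e_p_set & split.missing
    r_tpr = len(e_plus) / len(split.missing) if split.missing else 0.0
    r_ppv = len(e_plus) / len(e_p_set) if e_p_set else 0.0
    return r_tpr, r_ppv, e_plus
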