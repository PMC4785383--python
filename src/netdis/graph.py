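"""Undirected simple-graph statistics and edge-list I/O.

Networks are plain :class:`networkx.Graph` objects (simple, undirected,
unweighted).  This module supplies the structural statistics the rest of the
package consumes: degree maps, the Molloy–Reed-style ratio
``kappa = <k^2>/<k>`` whose drop below 2 marks the loss of the giant
component, component counts and relative giant-component size.

Node labels are opaque (ints or strings); no ordering between labels is
assumed beyond what is needed to canonicalise an undirected edge.
"""

from __future__ import annotations

import logging
from typing import Hashable, Iterable, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable
Edge = tuple[Node, Node]


def canonical_edge(u: Node, v: Node) -> Edge:
    """Return the unordered pair (u, v) in a canonical orientation.

    Within one network labels are homogeneous (all ints or all strings), so
    ``<`` is well defined; mixed-type labels fall back to string comparison.
    """
    try:
        return (u, v) if u <= v else (v, u)
    except TypeError:
        return (u, v) if str(u) <= str(v) else (v, u)


def canonical_edges(pairs: Iterable[tuple[Node, Node]]) -> frozenset[Edge]:
    """Canonicalise an iterable of unordered pairs into a frozenset."""
    return frozenset(canonical_edge(u, v) for u, v in pairs)


def degree_map(net: nx.Graph) -> dict[Node, int]:
    """Degree of every node, isolates included (degree 0)."""
    return dict(net.degree())


def kappa(net: nx.Graph) -> float:
    """Heterogeneity ratio ``<k^2>/<k>`` over the nodes currently in ``net``.

    The giant component of a random graph with a given degree sequence
    survives while kappa > 2 (Molloy–Reed criterion); the attack loop uses
    ``kappa < 2`` as the collapse test.  An edgeless graph has ``<k> = 0``
    and is reported as ``kappa = 0`` (collapsed) rather than an error,
    because the attack loop evaluates kappa after every removal including
    total destruction.

    Raises
    ------
    ValueError
        If the graph has no nodes.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("kappa is undefined for an empty node set")
    sum_k = 0
    sum_k2 = 0
    for _, k in net.degree():
        sum_k += k
        sum_k2 += k * k
    if sum_k == 0:
        return 0.0
    return sum_k2 / sum_k


def component_count(net: nx.Graph) -> int:
    """Number of connected components; isolated nodes each count as one."""
    if net.number_of_nodes() == 0:
        raise ValueError("component count is undefined for an empty node set")
    return nx.number_connected_components(net)


def giant_component_fraction(net: nx.Graph, n_ref: int) -> float:
    """Size of the largest component divided by a reference node count.

    ``n_ref`` is the node count of the *original* network, so nodes already
    removed by an attack count against the fraction S.
    """
    if n_ref < net.number_of_nodes():
        raise ValueError("n_ref must be at least the current node count")
    if net.number_of_nodes() == 0:
        return 0.0
    largest = max(len(c) for c in nx.connected_components(net))
    return largest / n_ref


def read_edgelist(source: str | TextIO) -> nx.Graph:
    """Read a whitespace-separated two-column edge list.

    Lines beginning with ``#`` are ignored.  Duplicate pairs and self-loops
    are dropped with a logged warning.  Labels are kept as strings unless
    every label parses as an integer, in which case all are converted.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    try:
        edges: list[tuple[str, str]] = []
        for lineno, line in enumerate(source, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
            edges.append((parts[0], parts[1]))
    finally:
        if close:
            source.close()

    labels = {u for e in edges for u in e}
    if labels and all(lbl.lstrip("-").isdigit() for lbl in labels):
        edges = [(int(u), int(v)) for u, v in edges]  # type: ignore[misc]

    g: nx.Graph = nx.Graph()
    n_loops = 0
    n_dups = 0
    for u, v in edges:
        if u == v:
            n_loops += 1
            continue
        if g.has_edge(u, v):
            n_dups += 1
            continue
        g.add_edge(u, v)
    if n_loops:
        logger.warning("dropped %d self-loop(s) from input edge list", n_loops)
    if n_dups:
        logger.warning("dropped %d duplicate edge(s) from input edge list", n_dups)
    return g


def write_edgelist(net: nx.Graph, target: str | TextIO) -> None:
    """Write one ``u v`` pair per line."""
    close = False
    if isinstance(target, str):
        target = open(target, "w")
        close = True
    try:
        for u, v in net.edges():
            target.write(f"{u} {v}\n")
    finally:
        if close:
            target.close()
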