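"""Static high-degree attack and the kappa-based collapse criterion.

Targets are ranked once by their degree in a *reference* network (the
observed or the link-prediction-improved network) and removed from the
*true* network in that fixed order — degrees are never recomputed during
the attack.  After each removal ``kappa = <k^2>/<k>`` is evaluated over the
surviving nodes; the first step at which ``kappa < 2`` (strictly) marks the
collapse, and the critical attack strength is ``f_c = t / N``.

The removal loop maintains the degree sums incrementally, so a full attack
costs O(N + W); the relative giant-component size S(f) is recovered by
replaying the removals backwards through a union-find, which keeps the full
trace at the same cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .graph import Node


@dataclass(frozen=True)
class AttackResult:
    """Trajectory of one attack: removal order, per-step kappa and S, collapse.

    ``kappa_trace[t-1]`` and ``s_trace[t-1]`` are the values after the t-th
    removal; ``t_collapse`` is the first removal count with kappa < 2
    (0 when the intact network is already below the threshold) and
    ``f_c = t_collapse / N``.
    """

    order: tuple[Node, ...]
    kappa_trace: np.ndarray
    s_trace: np.ndarray
    t_collapse: int
    f_c: float


def degree_ranking(
    ref_net: nx.Graph, rng: np.random.Generator
) -> list[Node]:
    """All nodes of the reference network, highest degree first.

    Equal degrees are ordered uniformly at random from the seeded stream;
    the ranking is static and is not revised as nodes are removed.
    """
    nodes = list(ref_net.nodes())
    perm = rng.permutation(len(nodes))
    shuffled = [nodes[i] for i in perm]
    shuffled.sort(key=lambda v: -ref_net.degree(v))
    return shuffled


class _AttackEngine:
    """Reusable incremental-kappa attack evaluator for one true network.

    Precomputes index arrays once so that many rankings (different
    tie-breaks, different reference networks) can be attacked cheaply.
    """

    def __init__(self, true_net: nx.Graph) -> None:
        self.nodes: list[Node] = list(true_net.nodes())
        self.index: dict[Node, int] = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.deg0 = np.array([true_net.degree(v) for v in self.nodes], dtype=np.int64)
        self.adj: list[np.ndarray] = [
            np.fromiter((self.index[u] for u in true_net[v]), dtype=np.int64)
            for v in self.nodes
        ]

    def order_to_idx(self, order: Sequence[Node]) -> np.ndarray:
        if len(order) < self.n or not all(v in self.index for v in order):
            missing = [v for v in self.nodes if v not in set(order)]
            raise ValueError(f"attack order does not cover the network: missing {missing[:5]}")
        return np.fromiter((self.index[v] for v in order), dtype=np.int64)

    def collapse_step(self, order_idx: np.ndarray) -> int:
        """First removal count t with kappa < 2 over the survivors."""
        deg = self.deg0.copy()
        alive = np.ones(self.n, dtype=bool)
        sum_k = int(deg.sum())
        sum_k2 = int((deg * deg).sum())
        if sum_k == 0 or sum_k2 < 2 * sum_k:
            return 0
        for t, i in enumerate(order_idx, start=1):
            d_i = int(deg[i])
            alive[i] = False
            sum_k -= d_i
            sum_k2 -= d_i * d_i
            for j in self.adj[i]:
                if alive[j]:
                    sum_k -= 1
                    sum_k2 -= 2 * int(deg[j]) - 1
                    deg[j] -= 1
            if sum_k == 0 or sum_k2 < 2 * sum_k:
                return t
        return self.n  # unreachable for f_max = 1: the empty graph has kappa 0

    def trace(
        self, order_idx: np.ndarray, n_steps: int
    ) -> tuple[np.ndarray, np.ndarray, int]:
        """Per-step kappa and giant-component fraction over n_steps removals."""
        deg = self.deg0.copy()
        alive = np.ones(self.n, dtype=bool)
        sum_k = int(deg.sum())
        sum_k2 = int((deg * deg).sum())
        collapsed_at = 0 if (sum_k == 0 or sum_k2 < 2 * sum_k) else -1
        kappa_trace = np.empty(n_steps)
        for t in range(1, n_steps + 1):
            i = order_idx[t - 1]
            d_i = int(deg[i])
            alive[i] = False
            sum_k -= d_i
            sum_k2 -= d_i * d_i
            for j in self.adj[i]:
                if alive[j]:
                    sum_k -= 1
                    sum_k2 -= 2 * int(deg[j]) - 1
                    deg[j] -= 1
            kappa_trace[t - 1] = sum_k2 / sum_k if sum_k else 0.0
            if collapsed_at < 0 and (sum_k == 0 or sum_k2 < 2 * sum_k):
                collapsed_at = t
        s_trace = self._giant_sizes(order_idx, n_steps) / self.n
        return kappa_trace, s_trace, collapsed_at

    def _giant_sizes(self, order_idx: np.ndarray, n_steps: int) -> np.ndarray:
        """Largest-component size after each of the first n_steps removals.

        Replays the removals in reverse: start from the survivors, then add
        the removed nodes back one at a time, merging components with a
        union-find and tracking the running maximum component size.
        """
        parent = np.arange(self.n)
        size = np.ones(self.n, dtype=np.int64)
        present = np.ones(self.n, dtype=bool)
        present[order_idx[:n_steps]] = False

        def find(x: int) -> int:
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        giant = 0

        def add_node(i: int) -> None:
            nonlocal giant
            present[i] = True
            giant = max(giant, 1)
            for j in self.adj[i]:
                if present[j]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        if size[ri] < size[rj]:
                            ri, rj = rj, ri
                        parent[rj] = ri
                        size[ri] += size[rj]
                        giant = max(giant, int(size[ri]))

        for i in np.flatnonzero(present):
            add_node(i)

        sizes = np.empty(n_steps, dtype=np.int64)
        for t in range(n_steps, 0, -1):
            sizes[t - 1] = giant
            add_node(int(order_idx[t - 1]))
        return sizes


def attack_sequence(
    true_net: nx.Graph, order: Sequence[Node], f_max: float = 1.0
) -> AttackResult:
    """Execute a static attack on the true network in the given order.

    Removes ``round(f_max * N)`` nodes one at a time (each node takes its
    attached links with it), recording kappa and the giant-component
    fraction S after every removal.  If the collapse threshold is not
    crossed within the recorded window the removals continue silently until
    it is, so ``t_collapse`` is always defined.
    """
    if not 0.0 < f_max <= 1.0:
        raise ValueError("f_max must lie in (0, 1]")
    engine = _AttackEngine(true_net)
    order_idx = engine.order_to_idx(order)
    n_steps = round(f_max * engine.n)
    kappa_trace, s_trace, t_collapse = engine.trace(order_idx, n_steps)
    if t_collapse < 0:
        t_collapse = engine.collapse_step(order_idx)
    return AttackResult(
        order=tuple(order),
        kappa_trace=kappa_trace,
        s_trace=s_trace,
        t_collapse=t_collapse,
        f_c=t_collapse / engine.n,
    )


def critical_fraction(
    true_net: nx.Graph,
    ref_net: nx.Graph,
    n_reps: int = 1,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean f_c over independent tie-breaking randomisations of the ranking.

    With no degree ties in the reference network a single repetition is
    exact; ties make f_c a random variable and the ensemble mean is the
    quantity of interest.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    engine = _AttackEngine(true_net)
    total = 0.0
    for _ in range(n_reps):
        order = degree_ranking(ref_net, rng)
        total += engine.collapse_step(engine.order_to_idx(order)) / engine.n
    return total / n_reps
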