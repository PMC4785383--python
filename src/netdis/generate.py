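"""Random scale-free network generation and the worked-example fixture.

Degree sequences are drawn from the continuous power-law density
``p(k) = (lambda-1) m^(lambda-1) k^(-lambda)`` on ``[m, inf)`` by inverse-CDF
sampling, floored to integers and capped at ``N-1``; the network is then
realised with a configuration model (uniform stub matching) and simplified
by discarding self-loops and parallel edges.  At the default parameters
(``N=1000, lambda=2.5, m=2``) the discarded fraction is small (a percent or
so), so the realised degree distribution tracks the target closely.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the power-law configuration-model ensemble.

    Attributes
    ----------
    n : int
        Node count N.
    lambda_exp : float
        Power-law exponent lambda (> 2 for a finite mean degree).
    m : int
        Minimum degree (lower bound of the continuous density).
    seed : int
        RNG seed; the generated network is a deterministic function of it.
    """

    n: int = 1000
    lambda_exp: float = 2.5
    m: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.m + 1:
            raise ValueError("need n >= m + 1")
        if self.lambda_exp <= 1:
            raise ValueError("lambda_exp must exceed 1")
        if self.m < 1:
            raise ValueError("m must be a positive integer")


def sample_power_law_degrees(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw N integer degrees from the floored, capped power law.

    Each degree is ``floor(m * (1-u)^(-1/(lambda-1)))`` for uniform ``u``,
    capped at ``N-1`` (a simple graph admits no larger degree).  If the sum
    is odd, one uniformly chosen entry below the cap is incremented so the
    sequence is graphical for stub matching.
    """
    u = rng.random(cfg.n)
    k = np.floor(cfg.m * (1.0 - u) ** (-1.0 / (cfg.lambda_exp - 1.0)))
    k = np.minimum(k, cfg.n - 1).astype(np.int64)
    if int(k.sum()) % 2 == 1:
        below_cap = np.flatnonzero(k < cfg.n - 1)
        k[rng.choice(below_cap)] += 1
    return k


def configuration_model(
    degrees: np.ndarray | list[int], rng: np.random.Generator
) -> nx.Graph:
    """Realise a degree sequence by uniform stub matching, then simplify.

    Self-loops and parallel edges produced by the matching are discarded
    (not rewired), so the realised degree of node i is at most the
    requested degree.  All nodes ``0..len(degrees)-1`` are present in the
    result, including any left isolated.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    total = int(degrees.sum())
    if total % 2 != 0:
        raise ValueError("degree sequence must have an even sum")
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    u, v = stubs[0::2], stubs[1::2]
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(range(len(degrees)))
    keep = u != v
    g.add_edges_from(zip(u[keep].tolist(), v[keep].tolist()))
    return g


def generate_scale_free(cfg: GeneratorConfig) -> nx.Graph:
    """Sample a degree sequence and realise it; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    degrees = sample_power_law_degrees(cfg, rng)
    return configuration_model(degrees, rng)


def five_node_example() -> nx.Graph:
    """The five-node, seven-link illustration network.

    Nodes A..E with degree sequence (k_A, .., k_E) = (1, 3, 3, 3, 4); the
    hub E touches every node but A's only neighbour is E.  Used throughout
    the tests as a hand-checkable worked example.
    """
    g: nx.Graph = nx.Graph()
    g.add_edges_from(
        [("A", "E"), ("B", "C"), ("B", "D"), ("B", "E"),
         ("C", "D"), ("C", "E"), ("D", "E")]
    )
    return g
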