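"""Shared fixtures: the five-node worked example and its fixed observation split."""

import numpy as np
import pytest

from netdis import ObservationSplit, five_node_example, observed_network


@pytest.fixture
def toy_net():
    """Five nodes A..E, seven links, degree sequence (1, 3, 3, 3, 4)."""
    return five_node_example()


@pytest.fixture
def toy_split(toy_net):
    """The fixed split hiding E_M = {CD, CE, DE}, so alpha = 3/7."""
    missing = frozenset({("C", "D"), ("C", "E"), ("D", "E")})
    observed = frozenset({("A", "E"), ("B", "C"), ("B", "D"), ("B", "E")})
    return ObservationSplit(observed=observed, missing=missing, alpha=3 / 7)


@pytest.fixture
def toy_observed(toy_net, toy_split):
    """G_O: all five nodes, only the four observed links."""
    return observed_network(toy_net, toy_split)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
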