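import networkx as nx
import numpy as np
import pytest

from mpinet import MetaboliteNetwork


def make_network(edges) -> MetaboliteNetwork:
    """Build a network from (a, b, weight) triples."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(str(a), str(b), weight=w)
    return MetaboliteNetwork(g)


def random_network(rng: np.random.Generator, n_nodes: int, p: float = 0.5):
    """Random connected-ish weighted graph for property tests."""
    g = nx.Graph()
    for i in range(n_nodes):
        g.add_node(str(i + 1))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(str(i + 1), str(j + 1), weight=float(rng.uniform(0.1, 1.0)))
    return MetaboliteNetwork(g)


@pytest.fixture
def path_network():
    """The 3-node worked example: 1-2 (0.9), 2-3 (0.8)."""
    return make_network([(1, 2, 0.9), (2, 3, 0.8)])


@pytest.fixture
def triangle_network():
    return make_network([(1, 2, 0.5), (2, 3, 0.6), (1, 3, 0.7)])
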