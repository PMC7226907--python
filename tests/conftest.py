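"""Shared fixtures: small deterministic graphs and session-scoped UCM networks."""

import networkx as nx
import numpy as np
import pytest

from cmpnet import Graph, NetworkSpec, generate_network


def random_graph(n: int, p: float, seed: int) -> Graph:
    """Erdos-Renyi graph as a cmpnet Graph (isolated nodes allowed)."""
    return Graph.from_networkx(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture(scope="session")
def ucm35_1e5() -> Graph:
    """UCM network, gamma=3.5, kmin=3, N=1e5, hard cutoff (shared across tests)."""
    return generate_network(
        NetworkSpec(gamma=3.5, kmin=3, N=10**5, cutoff_rule="hard", seed=11)
    )


@pytest.fixture(scope="session")
def ucm27_1e5() -> Graph:
    """UCM network, gamma=2.7, kmin=3, N=1e5, structural cutoff."""
    return generate_network(
        NetworkSpec(gamma=2.7, kmin=3, N=10**5, cutoff_rule="structural", seed=3)
    )


@pytest.fixture
def path5() -> Graph:
    """Path a-b-c-d-e with degrees 1,2,2,2,1."""
    return Graph.from_edges(5, [0, 1, 2, 3], [1, 2, 3, 4])


@pytest.fixture
def two_hubs_d2() -> Graph:
    """Two degree-10 hubs (nodes 0 and 1) at hop distance 2 via node 20."""
    g = nx.Graph()
    for leaf in range(2, 11):
        g.add_edge(0, leaf)
    for leaf in range(11, 20):
        g.add_edge(1, leaf)
    g.add_edge(0, 20)
    g.add_edge(1, 20)
    return Graph.from_networkx(g)


@pytest.fixture
def two_hubs_d3() -> Graph:
    """Two degree-5 hubs (nodes 0 and 1) at hop distance 3."""
    g = nx.Graph()
    for leaf in range(2, 6):
        g.add_edge(0, leaf)
    for leaf in range(6, 10):
        g.add_edge(1, leaf)
    g.add_edge(0, 10)
    g.add_edge(10, 11)
    g.add_edge(11, 1)
    return Graph.from_networkx(g)
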