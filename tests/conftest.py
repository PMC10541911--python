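import networkx as nx
import pytest

from hvgc import Graph, synthetic_graph, toy_network


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def toy_graph(toy):
    return toy.graph


def to_networkx(g: Graph) -> nx.Graph:
    """Independent-view conversion used by oracle checks."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges())
    return h


def random_er(seed: int, n: int = 20, p: float = 0.25) -> Graph:
    return synthetic_graph("ER", rng_seed=seed, n=n, p=p)


@pytest.fixture
def triangle():
    return Graph([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def star4():
    return Graph([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])


@pytest.fixture
def path3():
    return Graph([("a", "b"), ("b", "c")])
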