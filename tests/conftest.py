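import networkx as nx
import pytest

from clockrank.network_io import InteractionNetwork
from clockrank.synthetic import GeneratorConfig, generate


def net_from(edges, nodes=None) -> InteractionNetwork:
    return InteractionNetwork.from_edges(edges, nodes=nodes)


@pytest.fixture
def k2():
    return net_from([("a", "b")])


@pytest.fixture
def triangle():
    return net_from([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def path3():
    return net_from([("a", "b"), ("b", "c")])


@pytest.fixture
def star3():
    return net_from([("x", "a"), ("x", "b"), ("x", "c")])


@pytest.fixture(scope="session")
def karate():
    g = nx.karate_club_graph()
    return net_from((f"n{u}", f"n{v}") for u, v in g.edges())


#: scaled-down benchmark for fast end-to-end tests
SMALL_BENCH = GeneratorConfig(
    n_nodes=250,
    module_size=20,
    n_seeds=6,
    n_go_terms=20,
    n_pathway_terms=10,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_bench():
    return generate(SMALL_BENCH)
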