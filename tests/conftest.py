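import networkx as nx
import numpy as np
import pytest

from subcomplex.io import GoDag
from subcomplex.synthetic import SyntheticConfig, generate

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world():
    """The default synthetic world used across integration tests."""
    return generate(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def noiseless_world():
    """A world with exact homolog transfer (no dropout, no inserted terms)."""
    cfg = SyntheticConfig(homolog_dropout=0.0, homolog_noise=0.0)
    return generate(cfg, seed=WORLD_SEED)


@pytest.fixture(scope="session")
def stress_world():
    """A large world whose negative pools cover the printed sampling sizes."""
    cfg = SyntheticConfig(
        n_complexes=260,
        fully_fraction=0.3,
        partial_size=(12, 40, 0.1),
        periphery_fraction=0.45,
    )
    return generate(cfg, seed=WORLD_SEED)


def make_dag(edges, extra_terms=()):
    """GoDag from (child, parent, relation) triples."""
    dag = GoDag()
    for child, parent, relation in edges:
        for term in (child, parent):
            if term not in dag:
                dag.add_term(term)
        dag.add_edge(child, parent, relation)
    for term in extra_terms:
        if term not in dag:
            dag.add_term(term)
    dag.validate()
    return dag


@pytest.fixture
def two_triangles():
    """Two disjoint unweighted triangles: the canonical Q = 0.5 fixture."""
    net = nx.Graph()
    net.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return net


def random_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """A random small graph with at least one edge (occasionally weighted)."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.25, 0.9))
        net = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if net.number_of_edges() == 0:
            continue
        if rng.random() < 0.3:
            for u, v in net.edges:
                net[u][v]["weight"] = float(rng.integers(1, 4))
        return net
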