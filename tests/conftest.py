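import networkx as nx
import numpy as np
import pytest

from metnetwalk import (
    AssociationTable,
    SimilarityMatrix,
    SyntheticSpec,
    WMAN,
    generate_planted_associations,
)


@pytest.fixture
def toy_table():
    """Three pairs: d1-{m1,m2}, d2-{m2}."""
    return AssociationTable.from_pairs([("d1", "m1"), ("d1", "m2"), ("d2", "m2")])


@pytest.fixture(scope="session")
def planted():
    """The stated planted world: 4 groups, 40 diseases x 60 metabolites,
    p_in=0.8, p_out=0.02, seed 7."""
    spec = SyntheticSpec(
        n_diseases=40, n_metabolites=60, k_groups=4, p_in=0.8, p_out=0.02, rng_seed=7
    )
    return generate_planted_associations(spec)


@pytest.fixture(scope="session")
def planted_table(planted):
    return planted[0]


def random_connected_wman(rng: np.random.Generator, max_nodes: int = 50) -> WMAN:
    """A random connected weighted network for walk tests."""
    n = int(rng.integers(2, max_nodes + 1))
    while True:
        g = nx.gnp_random_graph(n, min(1.0, 3.0 / n + 0.1), seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            break
    h = nx.Graph()
    for u, v in g.edges:
        h.add_edge(f"n{u:03d}", f"n{v:03d}", weight=float(rng.uniform(0.05, 1.0)))
    return WMAN(graph=h)


def sim_from_dense(ids, values) -> SimilarityMatrix:
    return SimilarityMatrix(ids=tuple(ids), values=np.asarray(values, dtype=float))
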