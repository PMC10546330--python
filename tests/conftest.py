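import networkx as nx
import numpy as np
import pytest

from crossloc import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic dataset shared by read-only tests."""
    config = SyntheticConfig(rng_seed=11)
    network, truth, ontology, annotations = generate_all(config)
    return config, network, truth, ontology, annotations


@pytest.fixture()
def path_graph():
    g = nx.Graph()
    g.add_edge("A", "B")
    return g


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Largest connected component of a G(n, p) draw, string-labelled."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    lcc = max(nx.connected_components(g), key=len)
    g = g.subgraph(lcc).copy()
    return nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes()})
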