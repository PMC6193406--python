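import networkx as nx
import numpy as np
import pytest

from infomod import SimulationConfig, simulate_expression


def make_clique(graph: nx.Graph, names, weight: float = 1.0) -> None:
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            graph.add_edge(names[i], names[j], weight=weight)


@pytest.fixture(scope="session")
def barbell6() -> nx.Graph:
    """Two unit-weight triangles joined by a single edge."""
    g = nx.Graph()
    make_clique(g, ["a1", "a2", "a3"])
    make_clique(g, ["b1", "b2", "b3"])
    g.add_edge("a1", "b1", weight=1.0)
    return g


@pytest.fixture(scope="session")
def two_cliques8() -> tuple[nx.Graph, list[set]]:
    g = nx.Graph()
    left = [f"L{i}" for i in range(8)]
    right = [f"R{i}" for i in range(8)]
    make_clique(g, left)
    make_clique(g, right)
    g.add_edge("L0", "R0", weight=1.0)
    return g, [set(left), set(right)]


@pytest.fixture(scope="session")
def nested_benchmark() -> tuple[nx.Graph, dict]:
    """Two super-groups of two 8-cliques; dense bridges inside a super-group,
    one edge across super-groups."""
    g = nx.Graph()
    cliques = {}
    for s in "AB":
        for c in "12":
            names = [f"{s}{c}n{i}" for i in range(8)]
            cliques[s + c] = set(names)
            make_clique(g, names)
    for s in "AB":
        for i in range(4):
            g.add_edge(f"{s}1n{i}", f"{s}2n{i}", weight=1.0)
    g.add_edge("A1n7", "B1n7", weight=1.0)
    return g, cliques


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset shared by unit tests (module recovery scale)."""
    config = SimulationConfig(
        n_background_genes=30,
        super_blocks=[[12, 9], [10]],
        amplicon_size=4,
        n_tumor=80,
        n_normal=40,
        de_fraction=0.1,
        seed=5,
    )
    data, truth = simulate_expression(config)
    return config, data, truth


@pytest.fixture(scope="session")
def small_net(small_sim):
    """Top-k MI network of the small planted dataset."""
    from infomod import build_mi_table, prune_top_edges
    from infomod.simulate import suggested_top_edges

    config, data, truth = small_sim
    net = prune_top_edges(build_mi_table(data), suggested_top_edges(config))
    return net, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
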