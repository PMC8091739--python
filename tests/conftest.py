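import numpy as np
import pytest

from pin2target.pin_data import PINGraph, to_adjacency
from pin2target.synthetic_data import SyntheticConfig, generate_pin, plant_positives


@pytest.fixture
def path_graph():
    """a -> b -> c"""
    return PINGraph.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def bowtie_graph():
    """1 -> 2 <-> 3 -> 4: core {2,3}, input {1}, output {4}."""
    return PINGraph.from_edges([("1", "2"), ("2", "3"), ("3", "2"), ("3", "4")])


@pytest.fixture(scope="session")
def small_pin():
    """A modest synthetic PIN shared by metric tests."""
    return generate_pin(SyntheticConfig(n_nodes=120, edges_per_new_node=2, seed=7))


@pytest.fixture(scope="session")
def planted_pin():
    """Synthetic PIN with a strongly cohesive planted positive class, plus
    its adjacency matrix (session-scoped: several suites reuse it)."""
    config = SyntheticConfig(
        n_nodes=300, edges_per_new_node=3, n_positives=25,
        positive_cohesion=0.9, seed=11,
    )
    graph = generate_pin(config)
    positives = plant_positives(graph, config)
    return graph, positives, to_adjacency(graph), config


def random_digraph(n_nodes: int, edge_prob: float, rng: np.random.Generator) -> PINGraph:
    """Erdos-Renyi style directed graph used by oracle-equivalence suites."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and rng.random() < edge_prob
    ]
    return PINGraph.from_edges(edges, extra_nodes=names)
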