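import numpy as np
import pytest

from drugwalk.diffusion import DiffusionConfig
from drugwalk.types import GeneUniverse, SignedNetwork


@pytest.fixture
def chain_net():
    """Directed T -> A -> B with both edges inhibitory."""
    return SignedNetwork(nodes={"T", "A", "B"},
                         edges=[("T", "A", -1), ("A", "B", -1)], directed=True)


@pytest.fixture
def small_signed_net():
    """Undirected 6-node signed network used by walk/oracle tests."""
    edges = [("A", "B", 1), ("B", "C", -1), ("C", "D", 1), ("D", "E", -1),
             ("E", "F", 1), ("F", "A", -1), ("B", "E", 1), ("C", "F", -1)]
    return SignedNetwork(nodes=set("ABCDEF"), edges=edges, directed=False)


@pytest.fixture
def universe6():
    return GeneUniverse(sorted("ABCDEF"))


@pytest.fixture
def fast_diffusion():
    return DiffusionConfig(alpha=0.3, beta=0.95, epochs=15, steps=15, seed=0)


@pytest.fixture(scope="session")
def planted_world():
    """One standard planted world shared by the slower pipeline tests."""
    from drugwalk.experiments import make_world

    return make_world(seed=0)


@pytest.fixture(scope="session")
def planted_profiles(planted_world):
    from drugwalk.experiments import monte_carlo_profiles

    return monte_carlo_profiles(planted_world)


def random_signed_graph(rng, n_nodes=6, p_edge=0.6, inhib=0.4, directed=False):
    """Random connected-ish signed graph for property tests."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                sign = -1 if rng.random() < inhib else 1
                edges.append((nodes[i], nodes[j], sign))
    if not edges:
        edges = [(nodes[0], nodes[1], 1)]
    return SignedNetwork(nodes=set(nodes), edges=edges, directed=directed)
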