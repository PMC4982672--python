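import networkx as nx
import numpy as np
import pytest

import lacsnet as L
from lacsnet.cli import kcore_motif_graph


@pytest.fixture(scope="session")
def er_multiplex_small():
    """Identical-layer ER multiplex, 100 nodes, <k>=6."""
    g = L.generate_er_layer(100, 6.0, seed=11)
    return L.couple_layers(g, mode="identical")


@pytest.fixture(scope="session")
def er_multiplex_indep():
    """Independent-layer ER-ER multiplex, 120 nodes."""
    g1 = L.generate_er_layer(120, 6.0, seed=5)
    g2 = L.generate_er_layer(120, 6.0, seed=6)
    return L.couple_layers(g1, g2, mode="independent", seed=7)


@pytest.fixture(scope="session")
def motif_multiplex():
    """Identical-layer multiplex on the three-shell k-core motif."""
    return L.couple_layers(kcore_motif_graph(), mode="identical")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_simple_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.Graph:
    """Small Erdős–Rényi graph with random size and density."""
    n = int(rng.integers(1, max_nodes + 1))
    p = float(rng.random())
    return nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


def kcore_oracle(g: nx.Graph) -> dict:
    """Brute-force k-core indices by repeated minimum-degree pruning."""
    g = g.copy()
    core = {}
    k = 0
    while g.number_of_nodes():
        removed = True
        while removed:
            low = [v for v in g if g.degree(v) <= k]
            for v in low:
                core[v] = k
                g.remove_node(v)
            removed = bool(low)
        k += 1
    return core


def random_mmca_state(rng: np.random.Generator, n: int) -> L.MMCAState:
    """Valid random probability triple per node (Dirichlet rows)."""
    p = rng.dirichlet(np.ones(3), size=n)
    return L.MMCAState(p_us=p[:, 0], p_as=p[:, 1], p_ai=p[:, 2])
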