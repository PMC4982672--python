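"""Per-node heterogeneity: k-core decomposition, reduction factors and awareness thresholds.

Aware nodes are infected with a reduced probability ``beta_A = gamma_i * beta_U``;
unaware nodes become aware when the fraction of aware neighbours reaches a
local threshold ``alpha_i``.  Both per-node quantities are set by min-max
scaling a topological importance measure (degree or k-core index):
``gamma_i`` from the contagion layer, ``alpha_i`` from the awareness layer
under one of three correlation models (positive, negative, random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .multiplex import MultiplexNetwork

__all__ = [
    "NodeHeterogeneity",
    "kcore_index",
    "assign_gamma",
    "assign_alpha",
    "assign_heterogeneity",
    "MEASURES",
    "AWARENESS_MODELS",
]

MEASURES = ("degree", "kcore")
AWARENESS_MODELS = ("positive", "negative", "random")


@dataclass(frozen=True)
class NodeHeterogeneity:
    """Per-node reduction factors and awareness thresholds, plus provenance.

    ``gamma[i]`` multiplies the unaware infection probability for aware node
    ``i`` (0 = full protection, 1 = none) and depends only on the contagion
    layer; ``alpha[i]`` is the local awareness threshold and depends only on
    the awareness layer.
    """

    gamma: np.ndarray
    alpha: np.ndarray
    contagion_measure: str = "degree"
    awareness_measure: str = "degree"
    awareness_model: str = "positive"
    seed: int | None = None

    def __post_init__(self):
        for name, v in (("gamma", self.gamma), ("alpha", self.alpha)):
            v = np.asarray(v, dtype=np.float64)
            object.__setattr__(self, name, v)
            if v.min(initial=0.0) < 0 or v.max(initial=0.0) > 1:
                raise ValueError(f"{name} values must lie in [0, 1]")
        if self.gamma.shape != self.alpha.shape:
            raise ValueError("gamma and alpha must have equal length")

    @classmethod
    def homogeneous(cls, n: int, gamma: float, alpha: float) -> "NodeHeterogeneity":
        """Uniform parameters (the homogeneous special case of the model)."""
        return cls(
            gamma=np.full(n, gamma),
            alpha=np.full(n, alpha),
            contagion_measure="uniform",
            awareness_measure="uniform",
            awareness_model="uniform",
        )

    def to_table(self, node_ids) -> "list[tuple]":
        """(node id, gamma, alpha) rows for audit export."""
        return [
            (nid, float(g), float(a))
            for nid, g, a in zip(node_ids, self.gamma, self.alpha)
        ]


def _as_graph(g) -> nx.Graph:
    if isinstance(g, nx.Graph):
        return g
    return nx.from_scipy_sparse_array(sparse.csr_matrix(g))


def kcore_index(g) -> np.ndarray:
    """k-core (k-shell) index of every node.

    Node ``i`` gets the largest ``k_s`` such that it belongs to a maximal
    subgraph in which every node has internal degree >= ``k_s`` —
    equivalently, the round of the iterative pruning of all nodes with
    degree <= ``k_s`` at which it is removed.  Isolated nodes get 0.

    Accepts an adjacency matrix (result ordered by matrix index) or a
    ``networkx`` graph (ordered by ``list(g.nodes())``).
    """
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        return np.empty(0, dtype=np.int64)
    core = nx.core_number(graph)
    return np.array([core[v] for v in graph.nodes()], dtype=np.int64)


def _measure_values(net: MultiplexNetwork, layer: str, measure: str) -> np.ndarray:
    if measure == "degree":
        return net.degrees(layer).astype(np.float64)
    if measure == "kcore":
        adj = net.A if layer == "awareness" else net.B
        return kcore_index(adj).astype(np.float64)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def _minmax(values: np.ndarray, what: str) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        warnings.warn(
            f"{what}: measure is constant across nodes (regular graph); "
            "assigning 0.5 to every node",
            stacklevel=3,
        )
        return np.full(values.shape, 0.5)
    return (values - vmin) / (vmax - vmin)


def assign_gamma(net: MultiplexNetwork, measure: str = "degree") -> np.ndarray:
    """Reduction factor gamma_i = (m_i - m_min) / (m_max - m_min).

    The measure ``m`` (degree or k-core index) and its extrema are taken on
    the contagion layer: the least important node gets gamma = 0 (awareness
    fully blocks infection), the most important gets gamma = 1 (no
    protection).
    """
    if net.B.nnz == 0:
        raise ValueError("contagion layer has no edges")
    return _minmax(_measure_values(net, "contagion", measure), f"gamma[{measure}]")


def assign_alpha(
    net: MultiplexNetwork,
    measure: str = "degree",
    model: str = "positive",
    seed: int | None = None,
) -> np.ndarray:
    """Local awareness threshold alpha_i on the awareness layer.

    positive: alpha_i = (m_i - m_min)/(m_max - m_min)  (important nodes are
    hard to alert); negative: the exact complement; random: i.i.d.
    Uniform[0, 1) per node, drawn once from ``seed``.
    """
    if model == "random":
        return np.random.default_rng(seed).random(net.n_nodes)
    if net.A.nnz == 0:
        raise ValueError("awareness layer has no edges")
    scaled = _minmax(_measure_values(net, "awareness", measure), f"alpha[{measure}]")
    if model == "positive":
        return scaled
    if model == "negative":
        return 1.0 - scaled
    raise ValueError(f"unknown model {model!r}; expected one of {AWARENESS_MODELS}")


def assign_heterogeneity(
    net: MultiplexNetwork,
    contagion_measure: str = "degree",
    awareness_measure: str = "degree",
    model: str = "positive",
    seed: int | None = None,
) -> NodeHeterogeneity:
    """Bundle gamma and alpha for one experiment configuration."""
    return NodeHeterogeneity(
        gamma=assign_gamma(net, contagion_measure),
        alpha=assign_alpha(net, awareness_measure, model, seed),
        contagion_measure=contagion_measure,
        awareness_measure=awareness_measure,
        awareness_model=model,
        seed=seed,
    )
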