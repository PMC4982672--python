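"""Two-layer multiplex networks: container, synthetic generators and edge-list I/O.

A multiplex network here is a pair of unweighted, undirected simple graphs
(an *awareness* layer and a *contagion* layer) sharing one node set, with a
one-to-one correspondence between counterpart nodes.  Layers are stored as
sparse binary adjacency matrices over a common node ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = [
    "MultiplexNetwork",
    "LayeredEdgeList",
    "generate_sf_layer",
    "generate_er_layer",
    "couple_layers",
    "read_multiplex_edgelist",
    "write_multiplex_edgelist",
    "complete_layers",
]


def _graph_to_adjacency(g: nx.Graph, order: Sequence) -> sparse.csr_array:
    """Binary CSR adjacency of ``g`` in the given node order."""
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    rows, cols = [], []
    for u, v in g.edges():
        if u == v:
            continue
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
    data = np.ones(len(rows), dtype=np.float64)
    adj = sparse.csr_array((data, (rows, cols)), shape=(n, n))
    # collapse parallel entries introduced upstream, keep matrix binary
    adj.data[:] = 1.0
    adj.sum_duplicates()
    adj.data[:] = 1.0
    return adj


@dataclass(frozen=True)
class MultiplexNetwork:
    """Aligned two-layer multiplex network.

    Attributes
    ----------
    node_ids:
        Node labels in matrix order (row/column ``i`` of both layers is
        ``node_ids[i]``).
    A:
        Awareness-layer adjacency (symmetric, binary, zero diagonal).
    B:
        Contagion-layer adjacency (same conventions, same node order).
    """

    node_ids: tuple
    A: sparse.csr_array
    B: sparse.csr_array

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def degrees(self, layer: str) -> np.ndarray:
        """Integer degree sequence of ``layer`` ('awareness' or 'contagion')."""
        adj = self.A if layer == "awareness" else self.B
        return np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)

    def layer_graph(self, layer: str) -> nx.Graph:
        adj = self.A if layer == "awareness" else self.B
        g = nx.from_scipy_sparse_array(sparse.csr_matrix(adj))
        return nx.relabel_nodes(g, dict(enumerate(self.node_ids)))

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        n = self.n_nodes
        if n < 1:
            raise ValueError("multiplex network needs at least one node")
        for name, adj in (("awareness", self.A), ("contagion", self.B)):
            if adj.shape != (n, n):
                raise ValueError(f"{name} layer shape {adj.shape} != ({n},{n})")
            if (adj != adj.T).nnz:
                raise ValueError(f"{name} layer adjacency is not symmetric")
            if adj.diagonal().any():
                raise ValueError(f"{name} layer has self-loops")
            if adj.nnz and not np.all(adj.data == 1.0):
                raise ValueError(f"{name} layer adjacency is not binary")

    @classmethod
    def from_graphs(
        cls,
        awareness: nx.Graph,
        contagion: nx.Graph,
        node_order: Sequence | None = None,
    ) -> "MultiplexNetwork":
        """Build from two graphs defined over the same node set."""
        if set(awareness) != set(contagion):
            raise ValueError(
                "layers have different node sets; run complete_layers() first"
            )
        if node_order is None:
            node_order = list(awareness.nodes())
        net = cls(
            node_ids=tuple(node_order),
            A=_graph_to_adjacency(awareness, node_order),
            B=_graph_to_adjacency(contagion, node_order),
        )
        net.validate()
        return net


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------

def _truncated_powerlaw_mean(cut: int, kmax: int, exponent: float) -> float:
    k = np.arange(cut, kmax + 1, dtype=np.float64)
    w = k ** (-exponent)
    return float((k * w).sum() / w.sum())


def generate_sf_layer(
    n: int, exponent: float, mean_degree: float, seed: int | None = None
) -> nx.Graph:
    """Scale-free layer from the configuration model.

    Degrees are drawn from a discrete truncated power law
    ``P(k) ∝ k^-exponent`` on ``[k_cut, n-1]``.  No single integer lower
    cutoff gives an arbitrary target mean, so each node's cutoff is drawn
    from the two bracketing integers with the mixing probability that makes
    the expected mean degree equal ``mean_degree``.  Self-loops and parallel
    edges of the configuration-model multigraph are deleted (not rewired);
    the resulting distortion of the degree sequence is O(<k>^2/n).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if exponent <= 2:
        raise ValueError("need exponent > 2 (finite mean regime)")
    if not 0 < mean_degree <= n - 1:
        raise ValueError("need 0 < mean_degree <= n - 1")
    kmax = n - 1
    lo = 1
    m_lo = _truncated_powerlaw_mean(lo, kmax, exponent)
    if mean_degree < m_lo:
        raise ValueError(
            f"mean_degree={mean_degree} below the minimum {m_lo:.3f} reachable "
            f"with exponent={exponent}"
        )
    hi = lo
    m_hi = m_lo
    while m_hi < mean_degree:
        lo, m_lo = hi, m_hi
        hi += 1
        if hi > kmax:
            raise ValueError("mean_degree not reachable below the cutoff n-1")
        m_hi = _truncated_powerlaw_mean(hi, kmax, exponent)
    q = 0.0 if m_hi == m_lo else (mean_degree - m_lo) / (m_hi - m_lo)

    rng = np.random.default_rng(seed)
    use_hi = rng.random(n) < q
    degrees = np.empty(n, dtype=np.int64)
    for cut, mask in ((lo, ~use_hi), (hi, use_hi)):
        m = int(mask.sum())
        if not m:
            continue
        support = np.arange(cut, kmax + 1)
        pmf = support ** (-exponent)
        pmf /= pmf.sum()
        degrees[mask] = rng.choice(support, size=m, p=pmf)
    if degrees.sum() % 2:  # configuration model needs an even stub count
        degrees[rng.integers(n)] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def generate_er_layer(n: int, mean_degree: float, seed: int | None = None) -> nx.Graph:
    """Erdős–Rényi G(n, p) layer with p = mean_degree / (n - 1)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < mean_degree <= n - 1:
        raise ValueError("need 0 < mean_degree <= n - 1")
    p = mean_degree / (n - 1)
    return nx.fast_gnp_random_graph(n, p, seed=seed)


def couple_layers(
    layer1: nx.Graph,
    layer2: nx.Graph | None = None,
    mode: str = "identical",
    seed: int | None = None,
) -> MultiplexNetwork:
    """Pair two single layers into a multiplex network.

    ``identical`` duplicates ``layer1`` onto both layers (maximal positive
    interlayer degree correlation).  ``independent`` pairs ``layer1``
    (awareness) with ``layer2`` (contagion) after randomly permuting the
    node labels of ``layer2``, which destroys any interlayer degree
    correlation.
    """
    if mode == "identical":
        edge_set = lambda g: {frozenset(e) for e in g.edges()}
        if layer2 is not None and (
            set(layer2) != set(layer1) or edge_set(layer2) != edge_set(layer1)
        ):
            raise ValueError("identical mode requires layer2 absent or equal to layer1")
        order = list(layer1.nodes())
        adj = _graph_to_adjacency(layer1, order)
        net = MultiplexNetwork(node_ids=tuple(order), A=adj, B=adj.copy())
    elif mode == "independent":
        if layer2 is None:
            raise ValueError("independent mode requires a second layer")
        if layer1.number_of_nodes() != layer2.number_of_nodes():
            raise ValueError("independent mode requires equal node counts")
        rng = np.random.default_rng(seed)
        order1 = list(layer1.nodes())
        order2 = list(layer2.nodes())
        perm = rng.permutation(len(order2))
        paired = [order2[i] for i in perm]
        net = MultiplexNetwork(
            node_ids=tuple(order1),
            A=_graph_to_adjacency(layer1, order1),
            B=_graph_to_adjacency(layer2, paired),
        )
    else:
        raise ValueError(f"unknown coupling mode: {mode!r}")
    net.validate()
    return net


# ---------------------------------------------------------------------------
# multiplex edge-list I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayeredEdgeList:
    """Raw records of a multiplex edge-list file: (layer_id, u, v, weight).

    Weights are parsed but discarded when layers are converted to graphs
    (the dynamic model is unweighted and undirected).
    """

    records: tuple

    def layer_ids(self) -> list[int]:
        return sorted({r[0] for r in self.records})

    def layer_graph(self, layer_id: int) -> nx.Graph:
        """Simple graph of one layer: duplicates collapsed, self-loops dropped."""
        g = nx.Graph()
        for layer, u, v, _w in self.records:
            if layer != layer_id or u == v:
                continue
            g.add_edge(u, v)
        return g

    def stats(self) -> dict:
        """Parse statistics: distinct nodes/edges overall and per layer.

        Edges are counted as distinct undirected (layer, u, v) triples with
        self-loops excluded and reported separately, so printed dataset
        counts can be compared under an explicit convention.
        """
        nodes: set = set()
        edges: set = set()
        loops = 0
        per_layer: dict[int, dict] = {}
        for layer, u, v, _w in self.records:
            nodes.update((u, v))
            entry = per_layer.setdefault(layer, {"nodes": set(), "edges": set()})
            entry["nodes"].update((u, v))
            if u == v:
                loops += 1
                continue
            key = (layer,) + tuple(sorted((str(u), str(v))))
            edges.add(key)
            entry["edges"].add(key[1:])
        return {
            "n_nodes": len(nodes),
            "n_edges": len(edges),
            "n_self_loops": loops,
            "layers": {
                lid: {"n_nodes": len(d["nodes"]), "n_edges": len(d["edges"])}
                for lid, d in sorted(per_layer.items())
            },
        }


def read_multiplex_edgelist(
    path, layer_map: dict[str, int] | None = None
) -> tuple[LayeredEdgeList, dict[str, nx.Graph], dict]:
    """Read a multiplex edge-list text file.

    The format is one edge per line, whitespace separated:
    ``layer_id node_id node_id weight`` (weight optional); ``#`` starts a
    comment line.  Returns the raw record list, the two requested layers as
    (possibly node-set-mismatched) simple graphs keyed ``'awareness'`` /
    ``'contagion'``, and the parse statistics.  Pass the result to
    :func:`complete_layers` to obtain an aligned :class:`MultiplexNetwork`.
    """
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 'layer u v [weight]', got {line!r}"
                )
            try:
                layer = int(parts[0])
                weight = float(parts[3]) if len(parts) == 4 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append((layer, parts[1], parts[2], weight))
    edge_list = LayeredEdgeList(records=tuple(records))

    layers: dict[str, nx.Graph] = {}
    if layer_map is not None:
        present = set(edge_list.layer_ids())
        for role in ("awareness", "contagion"):
            if role not in layer_map:
                raise KeyError(f"layer_map must name a {role!r} layer id")
            lid = layer_map[role]
            if lid not in present:
                raise KeyError(f"layer id {lid} ({role}) not present in {path}")
            layers[role] = edge_list.layer_graph(lid)
    return edge_list, layers, edge_list.stats()


def write_multiplex_edgelist(path, layers: dict[int, nx.Graph]) -> None:
    """Write layers as 'layer u v 1' lines (unit weights, one edge per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# layer_id node_id node_id weight\n")
        for lid in sorted(layers):
            for u, v in layers[lid].edges():
                fh.write(f"{lid} {u} {v} 1\n")


def complete_layers(awareness: nx.Graph, contagion: nx.Graph) -> MultiplexNetwork:
    """Enforce one-to-one node correspondence between two layers.

    Any node present in only one layer is added to the other layer together
    with its incident edges from its home layer; existing edges are never
    duplicated.  Idempotent: aligned inputs pass through unchanged.
    """
    g_a = awareness.copy()
    g_c = contagion.copy()
    only_a = [v for v in g_a if v not in g_c]
    only_c = [v for v in g_c if v not in g_a]
    for v in only_a:
        g_c.add_node(v)
        g_c.add_edges_from(awareness.edges(v))
    for v in only_c:
        g_a.add_node(v)
        g_a.add_edges_from(contagion.edges(v))
    order = list(dict.fromkeys(itertools.chain(awareness, contagion)))
    return MultiplexNetwork.from_graphs(g_a, g_c, node_order=order)
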