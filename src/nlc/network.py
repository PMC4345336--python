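"""Undirected weighted network container.

The package works on undirected, optionally weighted multigraphs held as a
symmetric nonnegative weight matrix ``W``.  Edge weights are treated as
(expected) edge multiplicities, so a self-edge of weight ``s`` is stored as
``W[i, i] = 2 s`` — with that convention the degree of node ``i`` is exactly
the row sum ``d_i = sum_j W[i, j]`` and ``sum_i d_i = 2 m``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["Network"]


class Network:
    """An undirected weighted network.

    Parameters
    ----------
    W
        Symmetric n x n nonnegative weight matrix (dense or scipy sparse).
        Diagonal entries hold *twice* the self-edge weight.
    node_labels
        Ordered node labels; defaults to ``"0" .. "n-1"``.
    """

    def __init__(self, W, node_labels: Sequence[str] | None = None):
        W = sp.csr_array(W, dtype=float)
        if W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if (W < 0).nnz:
            raise ValueError("weight matrix must be nonnegative")
        if (abs(W - W.T) > 1e-9 * max(1.0, abs(W).max() if W.nnz else 1.0)).nnz:
            raise ValueError("weight matrix must be symmetric")
        self.W = W
        n = W.shape[0]
        if node_labels is None:
            node_labels = [str(i) for i in range(n)]
        if len(node_labels) != n:
            raise ValueError("node_labels length does not match matrix size")
        self.node_labels = [str(x) for x in node_labels]
        self._index = {lab: i for i, lab in enumerate(self.node_labels)}
        if len(self._index) != n:
            raise ValueError("node labels must be unique")
        # unordered edge arrays (i <= j), the workhorse for EM / map equation
        coo = sp.triu(self.W, format="coo")
        self.edge_i = coo.row.astype(np.intp)
        self.edge_j = coo.col.astype(np.intp)
        self.edge_w = coo.data.copy()
        # self-loops: W_ii = 2*weight of the self edge
        self.edge_w[self.edge_i == self.edge_j] /= 2.0

    # -- basic quantities --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of stored node pairs with positive weight (self-loops count once)."""
        return len(self.edge_w)

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree d_i = sum_j W_ij (weighted degree / strength)."""
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def total_weight(self) -> float:
        """Total link weight m, with sum_i d_i = 2 m."""
        return float(self.W.sum()) / 2.0

    def index_of(self, label: str) -> int:
        return self._index[str(label)]

    def dense(self) -> np.ndarray:
        return self.W.toarray()

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        node_labels: Sequence[str] | None = None,
    ) -> "Network":
        """Build from an iterable of ``(u, v)`` or ``(u, v, weight)`` tuples.

        Duplicate edges are summed into the pair weight.  Labels are opaque
        strings; ``node_labels`` fixes the node order (and may include
        isolated nodes), otherwise first-appearance order is used.
        """
        edges = [tuple(e) for e in edges]
        if node_labels is None:
            seen: dict[str, int] = {}
            for e in edges:
                for u in (str(e[0]), str(e[1])):
                    if u not in seen:
                        seen[u] = len(seen)
            node_labels = list(seen)
        labels = [str(x) for x in node_labels]
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        W = sp.dok_array((n, n), dtype=float)
        for e in edges:
            u, v = idx[str(e[0])], idx[str(e[1])]
            w = float(e[2]) if len(e) > 2 else 1.0
            if w < 0:
                raise ValueError("edge weights must be nonnegative")
            if u == v:
                W[u, u] += 2.0 * w
            else:
                W[u, v] += w
                W[v, u] += w
        return cls(W.tocsr(), labels)

    @classmethod
    def from_networkx(cls, graph: nx.Graph, weight: str | None = "weight") -> "Network":
        """Convert an undirected networkx graph (multi-edges summed)."""
        if graph.is_directed():
            raise ValueError("directed graphs are not supported; symmetrize first")
        labels = [str(u) for u in graph.nodes]
        edges = []
        for u, v, data in graph.edges(data=True):
            w = 1.0
            if weight is not None:
                w = float(data.get(weight, 1.0))
            edges.append((str(u), str(v), w))
        return cls.from_edges(edges, node_labels=labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for i, j, w in zip(self.edge_i, self.edge_j, self.edge_w):
            g.add_edge(self.node_labels[i], self.node_labels[j], weight=float(w))
        return g

    def subnetwork(self, labels: Sequence[str]) -> "Network":
        """Induced subnetwork on ``labels`` (internal edges only)."""
        keep = np.asarray([self.index_of(l) for l in labels], dtype=np.intp)
        sub = self.W[keep, :][:, keep]
        return Network(sub, [self.node_labels[i] for i in keep])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Network(n={self.n_nodes}, pairs={self.n_edges}, "
            f"m={self.total_weight:g})"
        )


def degree_sequence(net: Network) -> np.ndarray:
    """Per-node degrees d_i = sum_j W_ij, in node order."""
    return net.degrees
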