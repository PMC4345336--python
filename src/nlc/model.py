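"""Degree-allocation model of node and link communities.

Each of the ``c`` probabilistic communities is a configuration-model random
graph with no internal structure.  The only parameters are the expected
per-community degrees ``d_ik`` (node ``i``'s expected degree inside community
``k``), collected in an n x c matrix ``D`` subject to the defining constraint
``sum_k d_ik = d_i``: every node's observed degree is fully allocated across
communities.  Within community ``k`` the expected weight between ``i`` and
``j`` is the modularity null model restricted to that community,

    what_ijk = d_ik * d_jk / D_k,        D_k = sum_l d_lk,

and the whole network is the ensemble ``what_ij = sum_k what_ijk``.  Edge
weights are Poisson with these rates, which yields the log-likelihood (up to
constants)

    L = sum_{ordered pairs (i,j), incl. i=j} [ w_ij ln what_ij - what_ij ].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network

__all__ = ["DegreeModel", "Responsibilities", "expected_weight", "expected_matrix", "log_likelihood"]


@dataclass
class DegreeModel:
    """Expected per-community degrees d_ik.

    ``D[i, k] >= 0``; after fitting, each row sums to the node's observed
    degree.  Column sums ``D_k`` are derived, not stored.
    """

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("D must be a 2-D (n x c) array")
        if (self.D < 0).any():
            raise ValueError("expected degrees must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.D.shape[0]

    @property
    def n_communities(self) -> int:
        return self.D.shape[1]

    @property
    def community_degrees(self) -> np.ndarray:
        """Column sums D_k = sum_i d_ik (total expected degree per community)."""
        return self.D.sum(axis=0)

    def check_degree_constraint(self, net: Network, tol: float = 1e-6) -> None:
        """Verify sum_k d_ik = d_i within ``tol`` (relative on d_i >= 1)."""
        d = net.degrees
        err = np.abs(self.D.sum(axis=1) - d) / np.maximum(d, 1.0)
        if err.max(initial=0.0) > tol:
            raise ValueError(f"degree constraint violated, max rel err {err.max():.3g}")


@dataclass
class Responsibilities:
    """Posterior probabilities q_ij,k that edge (i, j) came from community k.

    Stored sparsely: row ``e`` of ``q`` corresponds to the network's unordered
    edge ``e`` (``net.edge_i[e], net.edge_j[e]``); each row sums to 1.
    """

    q: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if (self.q < 0).any():
            raise ValueError("responsibilities must be nonnegative")


def expected_weight(model: DegreeModel, i: int, j: int, k: int) -> float:
    """Expected weight d_ik d_jk / D_k between i and j inside community k.

    An empty community (D_k = 0) contributes 0 by convention.
    """
    Dk = model.D[:, k].sum()
    if Dk <= 0:
        return 0.0
    return float(model.D[i, k] * model.D[j, k] / Dk)


def expected_matrix(model: DegreeModel) -> np.ndarray:
    """Ensemble expected weights what_ij = sum_k d_ik d_jk / D_k (n x n)."""
    Dk = model.community_degrees
    pos = Dk > 0
    if not pos.any():
        return np.zeros((model.n_nodes, model.n_nodes))
    B = model.D[:, pos] / np.sqrt(Dk[pos])
    return B @ B.T


def _edge_rates(net: Network, model: DegreeModel) -> np.ndarray:
    """Per-community expected weight of every stored edge: (n_edges x c)."""
    Dk = model.community_degrees
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(Dk > 0, 1.0 / np.where(Dk > 0, Dk, 1.0), 0.0)
    return model.D[net.edge_i] * model.D[net.edge_j] * inv


def log_likelihood(net: Network, model: DegreeModel) -> float:
    """Poisson log-likelihood, constants dropped.

    The sum runs over ordered pairs including self-pairs; it reduces to

        sum_edges mult_e * w_e * ln what_e  -  sum_k D_k

    where ``mult_e`` is 2 for i != j and 1 for a self-pair (W_ii = 2 * self
    weight, so the self term w_ii ln what_ii appears once with w_ii).  Returns
    -inf if some observed edge has zero expected weight.
    """
    if model.n_nodes != net.n_nodes:
        raise ValueError("model/network size mismatch")
    rates = _edge_rates(net, model).sum(axis=1)
    w_full = np.where(net.edge_i == net.edge_j, 2.0 * net.edge_w, net.edge_w)
    mult = np.where(net.edge_i == net.edge_j, 1.0, 2.0)
    mask = w_full > 0
    if (rates[mask] <= 0).any():
        return -np.inf
    ll = float(np.sum(mult[mask] * w_full[mask] * np.log(rates[mask])))
    return ll - float(model.community_degrees.sum())
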