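"""Maximum-likelihood fitting of the degree-allocation model by EM.

E-step: posterior responsibility of community k for an observed edge (i, j),

    q_ij,k = (d_ik d_jk / D_k) / sum_l (d_il d_jl / D_l),

computed only for pairs with w_ij > 0.  M-step, from the Lagrange condition
of the auxiliary function under sum_k d_ik = d_i:

    d_ik = sum_j w_ij q_ij,k,

which satisfies the degree constraint exactly because sum_k q_ij,k = 1.
Alternating the two steps makes the log-likelihood monotonically
non-decreasing; the fit keeps the best of several random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DegreeModel, Responsibilities, _edge_rates, log_likelihood
from .network import Network

__all__ = ["init_params", "e_step", "m_step", "fit_em", "FitTrace"]


@dataclass
class FitTrace:
    """Objective values per iteration for each restart of a fit."""

    objective: list[np.ndarray] = field(default_factory=list)
    best_restart: int = 0

    @property
    def best(self) -> np.ndarray:
        return self.objective[self.best_restart]


def init_params(net: Network, c: int, rng: np.random.Generator | int | None = None) -> DegreeModel:
    """Random valid starting point: each degree split uniformly (Dirichlet)
    across the c communities, so the degree constraint holds exactly."""
    if c < 1:
        raise ValueError("need at least one community")
    rng = np.random.default_rng(rng)
    d = net.degrees
    if c == 1:
        return DegreeModel(d[:, None].copy())
    P = rng.dirichlet(np.ones(c), size=net.n_nodes)
    return DegreeModel(P * d[:, None])


def e_step(net: Network, model: DegreeModel) -> Responsibilities:
    """Posterior edge responsibilities under the current parameters."""
    rates = _edge_rates(net, model)
    tot = rates.sum(axis=1)
    bad = (tot <= 0) & (net.edge_w > 0)
    if bad.any():
        raise ValueError("degenerate model: an observed edge has zero expected weight")
    tot = np.where(tot > 0, tot, 1.0)
    return Responsibilities(rates / tot[:, None])


def m_step(net: Network, resp: Responsibilities) -> DegreeModel:
    """Closed-form update d_ik = sum_j w_ij q_ij,k (degree-constraint exact)."""
    q = resp.q
    c = q.shape[1]
    D = np.zeros((net.n_nodes, c))
    self_loop = net.edge_i == net.edge_j
    # W_ii = 2 * self weight contributes w_ii q_ii,k once to node i
    contrib_i = np.where(self_loop, 2.0 * net.edge_w, net.edge_w)[:, None] * q
    np.add.at(D, net.edge_i, contrib_i)
    off = ~self_loop
    np.add.at(D, net.edge_j[off], net.edge_w[off, None] * q[off])
    return DegreeModel(D)


def _structure_mdl(net: Network, model: DegreeModel) -> float:
    """Shortest description length achievable by typing ``model``'s
    communities.

    Used only to break ties between equal-likelihood optima: distinct global
    optima of the likelihood (e.g. a bridge edge explained equally well by
    either adjacent community) produce different hard structures, and the
    pipeline's own model-selection criterion prefers the shorter one.
    """
    from .inference import search_types  # runtime import: avoids module cycle

    _, _, mdl = search_types(net, model, mode="auto", seed=0)
    return mdl


def fit_em(
    net: Network,
    c: int,
    restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: np.random.Generator | int | None = None,
    tie_tol: float | None = None,
) -> tuple[DegreeModel, FitTrace]:
    """Fit by EM, best of ``restarts`` random initializations.

    Returns the model with the highest final log-likelihood and the
    per-restart objective traces.  Restarts whose final likelihoods agree to
    ``tie_tol`` (relative; default 100x the convergence tolerance, since
    differences below the stopping rule cannot be ranked) may still be
    *distinct* optima; such ties are broken toward the model whose best
    typed structure has the shortest description length, and remaining ties
    keep the earlier restart.
    """
    if c < 1:
        raise ValueError("need at least one community")
    if net.n_edges == 0:
        raise ValueError("cannot fit a network with no edges")
    rng = np.random.default_rng(seed)
    finals: list[tuple[float, int, DegreeModel]] = []
    trace = FitTrace()
    for r in range(restarts):
        model = init_params(net, c, rng)
        lls: list[float] = []
        ll = log_likelihood(net, model)
        for _ in range(max_iter):
            resp = e_step(net, model)
            model = m_step(net, resp)
            new_ll = log_likelihood(net, model)
            lls.append(new_ll)
            if abs(new_ll - ll) <= tol * max(abs(ll), 1.0):
                ll = new_ll
                break
            ll = new_ll
        trace.objective.append(np.asarray(lls))
        finals.append((ll, r, model))
        if c == 1:
            break
    if tie_tol is None:
        tie_tol = 100.0 * tol
    best_ll = max(f[0] for f in finals)
    tied = [f for f in finals if abs(f[0] - best_ll) <= tie_tol * max(abs(best_ll), 1.0)]
    if len(tied) > 1:
        # deduplicate numerically identical optima before scoring
        distinct: dict[bytes, tuple[float, int, DegreeModel]] = {}
        for f in tied:
            key = np.round(f[2].D, 4).tobytes()
            distinct.setdefault(key, f)
        tied = list(distinct.values())
    if len(tied) > 1:
        tied.sort(key=lambda f: (_structure_mdl(net, f[2]), f[1]))
    _, best_r, best_model = tied[0]
    trace.best_restart = best_r
    return best_model, trace
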