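"""Two-level map equation for possibly overlapping node covers.

The quality of a community structure is measured as the expected number of
bits per step needed to encode an infinite random walk on the network under
a two-level codebook: an index codebook announcing module entries, and one
codebook per module naming its nodes and its exit.  Regular structure
compresses the walk; the shorter the description length, the better the
cover.

Overlaps are handled with a module-memory random walk: the walker's state
is a (node, module) pair; at each step it moves to a neighbor j with
probability ``w_ij / d_i``, *keeps* its current module whenever j belongs to
it, and otherwise exits and enters one of j's modules uniformly.  The
within-module visit rates ``pi_ik`` are the stationary distribution of this
chain, and with module exit rates

    q_k = sum_{i in M_k} pi_ik * (sum_{j not in M_k} w_ij / d_i)

the description length in bits is the usual two-level expression

    L = q * H(Q) + sum_k p_k * H(P_k),

where ``q = sum_k q_k``, ``H(Q)`` is the entropy of the normalized exit
rates, ``p_k = q_k + sum_{i in M_k} pi_ik`` is the rate of use of module k's
codebook and ``P_k`` the normalized distribution over that module's exit
and node visit rates.  On a disjoint partition the stationary rates are the
ordinary ``p_i = d_i / 2m`` and this is exactly the classic two-level
undirected map equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import Network

__all__ = ["NodeCover", "induced_cover", "map_equation_mdl"]


@dataclass
class NodeCover:
    """A family of (possibly overlapping) node-label sets."""

    modules: list[frozenset]

    def __post_init__(self) -> None:
        self.modules = [frozenset(m) for m in self.modules]
        if any(len(m) == 0 for m in self.modules):
            raise ValueError("modules must be nonempty")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def membership_counts(self) -> dict:
        counts: dict = {}
        for m in self.modules:
            for u in m:
                counts[u] = counts.get(u, 0) + 1
        return counts

    def overlapping_nodes(self) -> frozenset:
        return frozenset(u for u, c in self.membership_counts().items() if c > 1)

    @classmethod
    def from_partition_labels(cls, labels: dict) -> "NodeCover":
        groups: dict = {}
        for u, g in labels.items():
            groups.setdefault(g, set()).add(u)
        return cls([frozenset(s) for s in groups.values()])


def induced_cover(structure, net: Network) -> NodeCover:
    """Node cover induced by a hybrid structure.

    A node community contributes its node set; a link community contributes
    the endpoints of its links (nodes inherit the memberships of their
    adjacent links).  Positive-degree nodes covered by no community become
    singleton modules, so the cover spans all positive-degree nodes.
    """
    modules = [m for m in structure.node_sets() if m]
    covered = set().union(*modules, set())
    deg = net.degrees
    for i, lab in enumerate(net.node_labels):
        if deg[i] > 0 and lab not in covered:
            modules.append(frozenset([lab]))
    return NodeCover(modules)


def _entropy(p: np.ndarray) -> float:
    """Entropy in bits of an unnormalized nonnegative vector after normalizing."""
    s = p.sum()
    if s <= 0:
        return 0.0
    p = p[p > 0] / s
    return float(-(p * np.log2(p)).sum())


def _stationary_rates(
    net: Network, modules: list[np.ndarray], tol: float = 1e-13, max_iter: int = 50000
) -> list[np.ndarray]:
    """Stationary visit rates of the module-memory walk, per module.

    States are (node, module) pairs for covered positive-degree nodes.  A
    step from (i, k) follows an edge to j with probability w_ij / d_i and
    keeps module k when j is in M_k, else enters one of j's modules
    uniformly.  The stationary distribution is found by (lazy, hence
    aperiodic) power iteration from the equal-split start p_i / o_i, which
    also fixes the per-connected-component masses at sum of d_i / 2m.
    """
    deg = net.degrees
    two_m = deg.sum()
    n_states = sum(len(m) for m in modules)
    state_of = {}  # (node, module index) -> state
    for k, mod in enumerate(modules):
        for i in mod:
            state_of[(int(i), k)] = len(state_of)
    o = np.zeros(net.n_nodes)
    for mod in modules:
        o[mod] += 1
    in_mod = [set(map(int, m)) for m in modules]
    mods_of: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for k, mod in enumerate(modules):
        for i in mod:
            mods_of[int(i)].append(k)
    rows, cols, vals = [], [], []
    for (i, k), s in state_of.items():
        start = net.W.indptr[i]
        stop = net.W.indptr[i + 1]
        for j, w in zip(net.W.indices[start:stop], net.W.data[start:stop]):
            pj = w / deg[i]
            if j in in_mod[k]:
                rows.append(state_of[(int(j), k)])
                cols.append(s)
                vals.append(pj)
            else:
                targets = mods_of[int(j)]
                for l in targets:
                    rows.append(state_of[(int(j), l)])
                    cols.append(s)
                    vals.append(pj / len(targets))
    T = sp.csr_array((vals, (rows, cols)), shape=(n_states, n_states))
    pi = np.empty(n_states)
    for (i, k), s in state_of.items():
        pi[s] = deg[i] / two_m / o[i]
    for _ in range(max_iter):
        new = 0.5 * (pi + T @ pi)
        if np.abs(new - pi).max() < tol:
            pi = new
            break
        pi = new
    out = []
    for k, mod in enumerate(modules):
        out.append(np.array([pi[state_of[(int(i), k)]] for i in mod]))
    return out


def _mdl_index_cover(net: Network, modules: list[np.ndarray]) -> float:
    """Map-equation description length for modules given as index arrays."""
    deg = net.degrees
    two_m = deg.sum()
    if two_m <= 0:
        raise ValueError("network has no edges")
    if not modules:
        raise ValueError("empty cover on a nonempty network")
    o = np.zeros(net.n_nodes)
    for mod in modules:
        o[mod] += 1
    if ((deg > 0) & (o == 0)).any():
        raise ValueError("cover must span all positive-degree nodes")
    # drop zero-degree nodes: they carry no flow
    modules = [mod[deg[mod] > 0] for mod in modules]
    modules = [mod for mod in modules if len(mod)]
    rates = _stationary_rates(net, modules)
    W = net.W
    exits = []
    module_terms = 0.0
    for mod, pm in zip(modules, rates):
        if pm.sum() <= 0:
            continue
        # fraction of each member's flow that leaves the module
        w_in = np.asarray(W[mod, :][:, mod].sum(axis=1)).ravel()
        out_frac = np.clip(1.0 - w_in / deg[mod], 0.0, 1.0)
        qk = float((pm * out_frac).sum())
        exits.append(qk)
        module_terms += (qk + pm.sum()) * _entropy(np.concatenate(([qk], pm)))
    exits = np.asarray(exits)
    q = exits.sum()
    index_term = q * _entropy(exits) if q > 0 else 0.0
    return index_term + module_terms


def map_equation_mdl(net: Network, cover: NodeCover, complete: bool = True) -> float:
    """Description length (bits/step) of a node cover on ``net``.

    ``complete=True`` first adds singleton modules for any positive-degree
    node the cover misses.
    """
    idx_modules = [
        np.asarray(sorted(net.index_of(u) for u in m), dtype=np.intp)
        for m in cover.modules
    ]
    if complete:
        covered = set()
        for m in idx_modules:
            covered.update(m.tolist())
        deg = net.degrees
        for i in range(net.n_nodes):
            if deg[i] > 0 and i not in covered:
                idx_modules.append(np.asarray([i], dtype=np.intp))
    return _mdl_index_cover(net, idx_modules)
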