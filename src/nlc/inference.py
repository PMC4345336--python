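"""From fitted parameters to hybrid node-link community structure.

A fitted model allocates every node's degree across communities.  Soft
memberships follow directly:

* node membership  S_i^k = d_ik / d_i  (the share of node i's degree devoted
  to community k);
* link membership  R_ij^k = what_ijk / sum_l what_ijl  (the posterior that
  edge (i, j) was generated inside community k).

Each community is then *typed* as either a node community (hard members =
nodes whose argmax membership is k) or a link community (hard members =
edges whose argmax membership is k), and the best assignment of types is the
one minimizing the map-equation description length of the induced node
cover — found exhaustively over the 2^c combinations when c is small, or by
a randomized local search that flips one community's type at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .em import fit_em
from .mapeq import NodeCover, _mdl_index_cover, map_equation_mdl
from .model import DegreeModel, _edge_rates
from .network import Network

__all__ = [
    "SoftMembership",
    "HybridStructure",
    "node_memberships",
    "link_memberships",
    "harden",
    "search_types",
    "detect_communities",
    "NLCResults",
]

NODE = "node"
LINK = "link"


@dataclass
class SoftMembership:
    """Probabilistic memberships: S (n x c, nodes) and R (edges x c, links).

    Row ``e`` of ``R`` corresponds to the network's stored edge ``e``.  Rows
    of positive-degree nodes / positive-weight edges sum to 1; zero-degree
    nodes have all-zero S rows.
    """

    S: np.ndarray
    R: np.ndarray


@dataclass
class HybridStructure:
    """Hard typed communities plus background.

    ``communities[k]`` is ``(type, members)`` with type ``"node"`` (members a
    frozenset of node labels) or ``"link"`` (members a frozenset of edges as
    sorted label pairs).  Background holds zero-degree / unassigned leftovers.
    """

    communities: list[tuple[str, frozenset]]
    background_nodes: frozenset
    background_links: frozenset

    @property
    def types(self) -> list[str]:
        return [t for t, _ in self.communities]

    def node_sets(self) -> list[frozenset]:
        """Node set covered by each community (endpoints for link type)."""
        out = []
        for t, members in self.communities:
            if t == NODE:
                out.append(members)
            else:
                out.append(frozenset(u for e in members for u in e))
        return out


def node_memberships(model: DegreeModel) -> np.ndarray:
    """S_i^k = d_ik / d_i; zero-degree rows are all zero (background)."""
    d = model.D.sum(axis=1)
    S = np.zeros_like(model.D)
    pos = d > 0
    S[pos] = model.D[pos] / d[pos, None]
    return S


def link_memberships(net: Network, model: DegreeModel) -> np.ndarray:
    """R_ij^k, row-aligned with the network's stored edges."""
    rates = _edge_rates(net, model)
    tot = rates.sum(axis=1)
    if ((tot <= 0) & (net.edge_w > 0)).any():
        raise ValueError("degenerate model: an observed edge has zero expected weight")
    tot = np.where(tot > 0, tot, 1.0)
    return rates / tot[:, None]


def _hard_assignments(net: Network, S: np.ndarray, R: np.ndarray):
    """Argmax community per positive-degree node and per edge (ties -> lowest k)."""
    d = S.sum(axis=1)
    node_assign = np.where(d > 0, S.argmax(axis=1), -1)
    link_assign = R.argmax(axis=1)
    return node_assign, link_assign


def harden(net: Network, S: np.ndarray, R: np.ndarray, types: list[str]) -> HybridStructure:
    """Hard typed communities from soft memberships under a type assignment.

    A node joins community k only if k is its argmax *and* k is node-typed;
    symmetrically for links.  Links whose argmax community is node-typed go
    to the background, as do nodes covered by no community (including all
    zero-degree nodes).
    """
    c = S.shape[1]
    if len(types) != c:
        raise ValueError("one type per community required")
    node_assign, link_assign = _hard_assignments(net, S, R)
    labels = net.node_labels
    communities: list[tuple[str, frozenset]] = []
    covered: set[str] = set()
    for k in range(c):
        if types[k] == NODE:
            members = frozenset(labels[i] for i in np.flatnonzero(node_assign == k))
            covered |= members
            communities.append((NODE, members))
        elif types[k] == LINK:
            es = np.flatnonzero(link_assign == k)
            edges = frozenset(
                tuple(sorted((labels[net.edge_i[e]], labels[net.edge_j[e]]))) for e in es
            )
            covered |= {u for e in edges for u in e}
            communities.append((LINK, edges))
        else:
            raise ValueError(f"unknown community type {types[k]!r}")
    all_edges = {
        tuple(sorted((labels[i], labels[j]))) for i, j in zip(net.edge_i, net.edge_j)
    }
    assigned_edges = set().union(*(m for t, m in communities if t == LINK), set())
    background_links = frozenset(all_edges - assigned_edges)
    background_nodes = frozenset(set(labels) - covered)
    return HybridStructure(communities, background_nodes, background_links)


def _index_cover_for_types(
    net: Network,
    node_assign: np.ndarray,
    link_assign: np.ndarray,
    types: tuple[str, ...] | list[str],
) -> list[np.ndarray]:
    """Induced node cover (index sets) for a type vector, empty modules dropped."""
    modules = []
    covered = np.zeros(net.n_nodes, dtype=bool)
    for k in range(len(types)):
        if types[k] == NODE:
            members = np.flatnonzero(node_assign == k)
        else:
            es = np.flatnonzero(link_assign == k)
            members = np.unique(np.concatenate([net.edge_i[es], net.edge_j[es]]))
        if len(members):
            modules.append(members)
            covered[members] = True
    # uncovered positive-degree nodes become singleton modules
    for i in np.flatnonzero((~covered) & (net.degrees > 0)):
        modules.append(np.array([i], dtype=np.intp))
    return modules


def search_types(
    net: Network,
    model: DegreeModel,
    mode: str = "auto",
    max_iter: int = 50,
    restarts: int = 5,
    seed: np.random.Generator | int | None = None,
    exhaustive_limit: int = 15,
) -> tuple[list[str], HybridStructure, float]:
    """Best type-per-community assignment by map-equation description length.

    ``mode="exhaustive"`` enumerates all 2^c combinations; ``"greedy"`` runs
    a local search flipping one type at a time from several starting points
    (all-node and all-link are always among them, so the result can never be
    worse than either pure scheme); ``"auto"`` picks exhaustive for
    c <= ``exhaustive_limit``.
    """
    S = node_memberships(model)
    R = link_memberships(net, model)
    node_assign, link_assign = _hard_assignments(net, S, R)
    c = model.n_communities

    def score(types) -> float:
        return _mdl_index_cover(
            net, _index_cover_for_types(net, node_assign, link_assign, types)
        )

    if mode == "auto":
        mode = "exhaustive" if c <= exhaustive_limit else "greedy"
    if mode == "exhaustive":
        best_types, best_mdl = None, np.inf
        for types in product((NODE, LINK), repeat=c):
            m = score(types)
            if m < best_mdl - 1e-12:
                best_mdl, best_types = m, list(types)
    elif mode == "greedy":
        rng = np.random.default_rng(seed)
        starts = [[NODE] * c, [LINK] * c]
        for _ in range(max(0, restarts - 2)):
            starts.append([NODE if b else LINK for b in rng.integers(0, 2, size=c)])
        best_types, best_mdl = None, np.inf
        for types in starts:
            types = list(types)
            cur = score(types)
            for _ in range(max_iter):
                improved = False
                for k in range(c):
                    flipped = list(types)
                    flipped[k] = LINK if types[k] == NODE else NODE
                    m = score(flipped)
                    if m < cur - 1e-12:
                        types, cur = flipped, m
                        improved = True
                if not improved:
                    break
            if cur < best_mdl - 1e-12:
                best_mdl, best_types = cur, types
    else:
        raise ValueError("mode must be 'auto', 'exhaustive' or 'greedy'")
    structure = harden(net, S, R, best_types)
    return best_types, structure, float(best_mdl)


@dataclass
class NLCResults:
    """Fitted hybrid community structure and everything used to derive it."""

    net: Network
    model: DegreeModel
    S: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    types: list[str]
    structure: HybridStructure
    cover: NodeCover
    mdl: float
    log_likelihood: float
    scheme: str = "hybrid"
    method: str = "em"
    seed: int | None = None
    trace: object | None = field(default=None, repr=False)

    @property
    def n_communities(self) -> int:
        return self.model.n_communities

    def summary(self) -> str:
        lines = [
            "Node-link community detection results",
            "=" * 48,
            f"nodes: {self.net.n_nodes}   total link weight: {self.net.total_weight:g}",
            f"communities: {self.n_communities}   scheme: {self.scheme}   method: {self.method}",
            f"log-likelihood: {self.log_likelihood:.4f}",
            f"description length: {self.mdl:.4f} bits/step",
            "-" * 48,
        ]
        for k, (t, members) in enumerate(self.structure.communities):
            if t == NODE:
                show = sorted(members)
                lines.append(f"[{k}] node community ({len(members)} nodes): "
                             + " ".join(map(str, show[:12]))
                             + (" ..." if len(show) > 12 else ""))
            else:
                nodes = sorted({u for e in members for u in e})
                lines.append(f"[{k}] link community ({len(members)} links over "
                             f"{len(nodes)} nodes): " + " ".join(map(str, nodes[:12]))
                             + (" ..." if len(nodes) > 12 else ""))
        if self.structure.background_nodes:
            lines.append(f"background nodes: {len(self.structure.background_nodes)}")
        if self.structure.background_links:
            lines.append(f"background links: {len(self.structure.background_links)}")
        return "\n".join(lines)


def detect_communities(
    net: Network,
    c: int,
    scheme: str = "hybrid",
    method: str = "em",
    restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
    type_mode: str = "auto",
) -> NLCResults:
    """End-to-end driver: fit the model, infer memberships, type communities.

    ``scheme`` forces all communities node-typed (``"node"``), link-typed
    (``"link"``), or searches the best mixture (``"hybrid"``).
    """
    from .model import log_likelihood as _ll

    if method == "em":
        model, trace = fit_em(net, c, restarts=restarts, max_iter=max_iter, tol=tol, seed=seed)
    elif method == "nmf":
        from .nmf import fit_nmf

        model, trace = fit_nmf(net, c, restarts=restarts, seed=seed)
    else:
        raise ValueError("method must be 'em' or 'nmf'")
    S = node_memberships(model)
    R = link_memberships(net, model)
    if scheme == "hybrid":
        types, structure, mdl = search_types(net, model, mode=type_mode, seed=seed)
    elif scheme in (NODE, LINK):
        types = [scheme] * c
        structure = harden(net, S, R, types)
        node_assign, link_assign = _hard_assignments(net, S, R)
        mdl = _mdl_index_cover(
            net, _index_cover_for_types(net, node_assign, link_assign, types)
        )
    else:
        raise ValueError("scheme must be 'node', 'link' or 'hybrid'")
    from .mapeq import induced_cover

    cover = induced_cover(structure, net)
    return NLCResults(
        net=net,
        model=model,
        S=S,
        R=R,
        types=types,
        structure=structure,
        cover=cover,
        mdl=float(mdl),
        log_likelihood=_ll(net, model),
        scheme=scheme,
        method=method,
        seed=seed,
        trace=trace,
    )
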