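"""Choosing the number of communities.

Small networks: sweep the community count c and keep the structure with the
shortest map-equation description length.  Large networks: recursively
bipartition, accepting a split only when it shortens the global description
length of the assembled partition, then re-search community types once on
the final structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import fit_em
from .inference import NLCResults, detect_communities
from .mapeq import _mdl_index_cover
from .network import Network

__all__ = ["sweep_c", "recursive_bipartition", "SweepResult"]


@dataclass
class SweepResult:
    """Best detection across a range of community counts, plus the curve."""

    best: NLCResults
    c_values: list[int]
    mdl_values: list[float]

    @property
    def best_c(self) -> int:
        return self.best.n_communities


def sweep_c(
    net: Network,
    c_min: int,
    c_max: int,
    scheme: str = "hybrid",
    method: str = "em",
    seed: int | None = None,
    **opts,
) -> SweepResult:
    """Fit at every c in [c_min, c_max]; return the argmin-MDL result.

    Ties keep the smallest c.  The full MDL-vs-c curve is returned for
    inspection/plotting.
    """
    if not (1 <= c_min <= c_max):
        raise ValueError("need 1 <= c_min <= c_max")
    results = []
    rng = np.random.default_rng(seed)
    for c in range(c_min, c_max + 1):
        sub_seed = int(rng.integers(2**31 - 1))
        results.append(
            detect_communities(net, c, scheme=scheme, method=method, seed=sub_seed, **opts)
        )
    mdls = [r.mdl for r in results]
    best = results[int(np.argmin(mdls))]
    return SweepResult(best, list(range(c_min, c_max + 1)), mdls)


def _bipartition_labels(
    net: Network, part: list[str], seed: int, restarts: int, max_iter: int,
    method: str = "em",
) -> tuple[list[str], list[str]] | None:
    """Split one part in two by a c=2 fit hardened with all-node typing."""
    sub = net.subnetwork(part)
    if sub.n_edges == 0:
        return None
    if method == "nmf":
        from .nmf import fit_nmf

        model, _ = fit_nmf(sub, 2, restarts=restarts, seed=seed)
    else:
        model, _ = fit_em(sub, 2, restarts=restarts, max_iter=max_iter, seed=seed)
    S = model.D / np.maximum(model.D.sum(axis=1), 1e-300)[:, None]
    assign = S.argmax(axis=1)
    left = [sub.node_labels[i] for i in np.flatnonzero(assign == 0)]
    right = [sub.node_labels[i] for i in np.flatnonzero(assign == 1)]
    if not left or not right:
        return None
    return left, right


def recursive_bipartition(
    net: Network,
    method: str = "em",
    min_size: int = 3,
    restarts: int = 10,
    max_iter: int = 500,
    seed: int | None = None,
    scheme: str = "hybrid",
) -> NLCResults:
    """Divisive detection without choosing c in advance.

    Starting from one part holding every positive-degree node, repeatedly
    try to split a part with a c=2 fit; a split is accepted only if it
    lowers the map-equation description length of the whole assembled
    partition.  Parts smaller than ``min_size`` are left alone.  The final
    part count becomes c, and a full fit at that c (with type search under
    ``scheme``) produces the returned result.
    """
    rng = np.random.default_rng(seed)
    deg = net.degrees
    parts: list[list[str]] = [
        [lab for i, lab in enumerate(net.node_labels) if deg[i] > 0]
    ]
    frozen: list[bool] = [False]

    def global_mdl(candidate: list[list[str]]) -> float:
        modules = [
            np.asarray(sorted(net.index_of(u) for u in part), dtype=np.intp)
            for part in candidate
        ]
        return _mdl_index_cover(net, modules)

    current = global_mdl(parts)
    while not all(frozen):
        k = frozen.index(False)
        part = parts[k]
        if len(part) < max(min_size, 2):
            frozen[k] = True
            continue
        split = _bipartition_labels(
            net, part, seed=int(rng.integers(2**31 - 1)), restarts=restarts,
            max_iter=max_iter, method=method,
        )
        if split is None:
            frozen[k] = True
            continue
        candidate = parts[:k] + [split[0], split[1]] + parts[k + 1 :]
        cand_mdl = global_mdl(candidate)
        if cand_mdl < current - 1e-12:
            parts = candidate
            frozen = frozen[:k] + [False, False] + frozen[k + 1 :]
            current = cand_mdl
        else:
            frozen[k] = True

    # Final model: polish the discovered partition with EM started from a
    # slightly smoothed partition indicator (exact zeros would make cross-part
    # edges inexplicable), then search community types once at the end.
    c = len(parts)
    from .em import e_step, m_step
    from .inference import (
        _hard_assignments,
        _index_cover_for_types,
        harden,
        link_memberships,
        node_memberships,
        search_types,
    )
    from .model import DegreeModel, log_likelihood

    P = np.full((net.n_nodes, c), 0.05 / c)
    for k, part in enumerate(parts):
        for lab in part:
            P[net.index_of(lab), k] += 0.95
    model = DegreeModel(P / P.sum(axis=1)[:, None] * deg[:, None])
    ll = log_likelihood(net, model)
    for _ in range(max_iter):
        model = m_step(net, e_step(net, model))
        new_ll = log_likelihood(net, model)
        if abs(new_ll - ll) <= 1e-8 * max(abs(ll), 1.0):
            ll = new_ll
            break
        ll = new_ll
    S = node_memberships(model)
    R = link_memberships(net, model)
    if scheme == "hybrid":
        types, structure, mdl = search_types(net, model, seed=seed)
    else:
        types = [scheme] * c
        structure = harden(net, S, R, types)
        na, la = _hard_assignments(net, S, R)
        mdl = _mdl_index_cover(net, _index_cover_for_types(net, na, la, types))
    from .mapeq import induced_cover

    return NLCResults(
        net=net, model=model, S=S, R=R, types=types, structure=structure,
        cover=induced_cover(structure, net), mdl=float(mdl),
        log_likelihood=ll, scheme=scheme, method=method, seed=seed,
    )
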