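"""Evaluation measures for (possibly overlapping) community structures.

* :func:`overlapping_nmi` — normalized mutual information extended to node
  covers: each community is a binary node-membership variable, conditional
  entropies are minimized over best-matching communities with a no-match
  guard, and the two directions are averaged symmetrically.
* :func:`extended_modularity` — modularity generalized to covers by
  down-weighting each node pair by the product of membership counts.
* :func:`enrichment` — within-community mean pairwise similarity over the
  network-wide mean.
* :func:`rescale_mdl` — linear 0-1 rescaling of description lengths between
  a baseline and an optimal value.
* :func:`sample_subnetwork` — ego-style sampler of ground-truth overlapping
  subnetworks with an extended-modularity quality filter.
"""

from __future__ import annotations

import numpy as np

from .mapeq import NodeCover
from .network import Network

__all__ = [
    "overlapping_nmi",
    "extended_modularity",
    "enrichment",
    "rescale_mdl",
    "sample_subnetwork",
]


def _h(p: float) -> float:
    """Binary entropy contribution -p log2 p with h(0) = 0."""
    return 0.0 if p <= 0.0 else float(-p * np.log2(p))


def _cover_matrix(cover: NodeCover, universe: list) -> np.ndarray:
    idx = {u: i for i, u in enumerate(universe)}
    M = np.zeros((cover.n_modules, len(universe)), dtype=bool)
    for k, mod in enumerate(cover.modules):
        for u in mod:
            if u not in idx:
                raise ValueError(f"node {u!r} not in the common node universe")
            M[k, idx[u]] = True
    return M


def _conditional_entropy_norm(X: np.ndarray, Y: np.ndarray, n: int) -> float:
    """Mean over rows of X of H(X_k | Y) / H(X_k), with the no-match guard.

    H(X_k | Y_l) = H(X_k, Y_l) - H(Y_l) is admitted only when
    h(p11) + h(p00) >= h(p01) + h(p10); if no Y_l is admissible the
    unconditional H(X_k) is used, so unrelated covers score near 1.
    """
    total = 0.0
    for xk in X:
        a = xk.sum() / n
        HX = _h(a) + _h(1 - a)
        if HX == 0.0:
            continue  # degenerate community (all or no nodes): carries no information
        best = HX
        for yl in Y:
            p11 = np.logical_and(xk, yl).sum() / n
            p10 = np.logical_and(xk, ~yl).sum() / n
            p01 = np.logical_and(~xk, yl).sum() / n
            p00 = 1.0 - p11 - p10 - p01
            if _h(p11) + _h(p00) < _h(p01) + _h(p10):
                continue  # no-match guard: complements must not masquerade as matches
            b = yl.sum() / n
            HY = _h(b) + _h(1 - b)
            Hcond = _h(p11) + _h(p10) + _h(p01) + _h(p00) - HY
            best = min(best, Hcond)
        total += best / HX
    return total / len(X)


def overlapping_nmi(cover_a: NodeCover, cover_b: NodeCover, universe) -> float:
    """NMI between two node covers over a common node universe, in [0, 1].

    Equals 1 iff the covers are identical up to community order; symmetric
    in its arguments and invariant to node relabeling.
    """
    universe = list(universe)
    n = len(universe)
    if n == 0:
        raise ValueError("empty node universe")
    A = _cover_matrix(cover_a, universe)
    B = _cover_matrix(cover_b, universe)
    hab = _conditional_entropy_norm(A, B, n)
    hba = _conditional_entropy_norm(B, A, n)
    return 1.0 - 0.5 * (hab + hba)


def extended_modularity(net: Network, cover: NodeCover) -> float:
    """EQ = (1/2m) sum_k sum_{i,j in C_k} [w_ij - d_i d_j / 2m] / (O_i O_j).

    ``O_i`` is the number of communities containing i; on a disjoint
    partition this is exactly standard modularity.
    """
    if cover.n_modules == 0:
        raise ValueError("empty cover")
    d = net.degrees
    two_m = d.sum()
    if two_m <= 0:
        raise ValueError("network has no edges")
    O = np.zeros(net.n_nodes)
    mods = []
    for mod in cover.modules:
        idx = np.asarray(sorted(net.index_of(u) for u in mod), dtype=np.intp)
        O[idx] += 1
        mods.append(idx)
    total = 0.0
    for idx in mods:
        W_sub = net.W[idx, :][:, idx].toarray()
        null = np.outer(d[idx], d[idx]) / two_m
        inv_o = 1.0 / O[idx]
        total += float((np.outer(inv_o, inv_o) * (W_sub - null)).sum())
    return total / two_m


def enrichment(cover: NodeCover, similarity, universe) -> float:
    """Within-community mean pairwise similarity over the global mean.

    ``similarity(u, v)`` is a symmetric 0/1 (or bounded) pair function.
    Within-community pairs are pooled across communities (a pair in several
    communities counts once per community); unordered pairs throughout.
    """
    universe = list(universe)
    pairs_all = [
        (u, v) for a, u in enumerate(universe) for v in universe[a + 1 :]
    ]
    if not pairs_all:
        raise ValueError("need at least two nodes")
    overall = np.mean([similarity(u, v) for u, v in pairs_all])
    within = []
    for mod in cover.modules:
        ms = sorted(mod)
        for a, u in enumerate(ms):
            for v in ms[a + 1 :]:
                within.append(similarity(u, v))
    if not within:
        raise ValueError("cover has no within-community pairs")
    if overall == 0:
        raise ValueError("network-wide mean similarity is zero")
    return float(np.mean(within) / overall)


def rescale_mdl(value: float, optimal: float, baseline: float) -> float:
    """Linear rescaling mapping ``baseline`` to 0 and ``optimal`` to 1."""
    if baseline == optimal:
        raise ValueError("baseline and optimal MDL coincide")
    return (baseline - value) / (baseline - optimal)


def _preprocess_ground_truth(cover: NodeCover) -> NodeCover:
    """Drop duplicate communities and communities of <= 2 nodes."""
    seen: set[frozenset] = set()
    modules = []
    for mod in cover.modules:
        if len(mod) <= 2 or mod in seen:
            continue
        seen.add(mod)
        modules.append(mod)
    if not modules:
        raise ValueError("no communities left after preprocessing")
    return NodeCover(modules)


def sample_subnetwork(
    net: Network,
    ground_truth: NodeCover,
    seed: int | np.random.Generator | None = None,
    eq_threshold: float = 0.1,
):
    """Ego-style overlapping-subnetwork sample around a multi-membership node.

    Ground truth is first preprocessed (duplicates merged, communities of at
    most two nodes dropped).  A node ``u`` with at least two memberships is
    drawn uniformly; the sample is the subgraph induced by all nodes sharing
    at least one community with ``u``, with the ground truth restricted to
    it.  Returns ``(subnetwork, restricted_cover)``, or ``None`` when the
    restricted cover's extended modularity falls below ``eq_threshold``
    (no well-defined community structure).
    """
    rng = np.random.default_rng(seed)
    gt = _preprocess_ground_truth(ground_truth)
    counts = gt.membership_counts()
    eligible = sorted(u for u, c in counts.items() if c >= 2)
    if not eligible:
        raise ValueError("ground truth has no node with two or more memberships")
    u = eligible[rng.integers(len(eligible))]
    keep = set()
    for mod in gt.modules:
        if u in mod:
            keep |= set(mod)
    keep_sorted = [lab for lab in net.node_labels if lab in keep]
    sub = net.subnetwork(keep_sorted)
    restricted = [frozenset(m & keep) for m in gt.modules]
    restricted = [m for m in restricted if len(m) >= 1]
    sub_cover = NodeCover(restricted)
    if extended_modularity(sub, sub_cover) < eq_threshold:
        return None
    return sub, sub_cover
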