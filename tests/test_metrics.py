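"""Cover-quality metrics: overlapping NMI, extended modularity, enrichment,
MDL rescaling and the ground-truth subnetwork sampler."""

from math import log2

import networkx as nx
import numpy as np
import pytest

import nlc
from nlc.mapeq import NodeCover
from nlc.metrics import (
    enrichment,
    extended_modularity,
    overlapping_nmi,
    rescale_mdl,
    sample_subnetwork,
)
from nlc.network import Network


def brute_force_nmi(cover_a, cover_b, universe):
    """Independent evaluation of the per-community binary-variable NMI."""
    n = len(universe)

    def h(p):
        return -p * log2(p) if p > 0 else 0.0

    def cond_norm(X, Y):
        vals = []
        for xk in X:
            px = len(xk) / n
            HX = h(px) + h(1 - px)
            if HX == 0:
                continue
            best = HX
            for yl in Y:
                p11 = len(xk & yl) / n
                p10 = len(xk - yl) / n
                p01 = len(yl - xk) / n
                p00 = 1 - p11 - p10 - p01
                if h(p11) + h(p00) < h(p01) + h(p10):
                    continue
                py = len(yl) / n
                best = min(best, h(p11) + h(p10) + h(p01) + h(p00) - (h(py) + h(1 - py)))
            vals.append(best / HX)
        return float(np.mean(vals))

    A = [set(m) for m in cover_a.modules]
    B = [set(m) for m in cover_b.modules]
    return 1 - 0.5 * (cond_norm(A, B) + cond_norm(B, A))


class TestOverlappingNMI:
    def test_identical_covers_score_one(self):
        cov = NodeCover([{"a", "b"}, {"b", "c", "d"}])
        assert overlapping_nmi(cov, cov, "abcd") == pytest.approx(1.0)

    def test_hand_built_covers_match_brute_force(self):
        U = list("abcdef")
        A = NodeCover([{"a", "b", "c"}, {"c", "d", "e", "f"}])
        B = NodeCover([{"a", "b"}, {"c", "d", "e"}, {"e", "f"}])
        val = overlapping_nmi(A, B, U)
        assert val == pytest.approx(0.44531455578156565, abs=1e-12)
        assert val == pytest.approx(brute_force_nmi(A, B, U), abs=1e-12)

    def test_symmetric_and_order_invariant(self):
        U = list("abcdefgh")
        rng = np.random.default_rng(0)
        A = NodeCover([frozenset(rng.choice(U, 4, replace=False)) for _ in range(3)])
        B = NodeCover([frozenset(rng.choice(U, 3, replace=False)) for _ in range(2)])
        assert overlapping_nmi(A, B, U) == pytest.approx(overlapping_nmi(B, A, U))
        A2 = NodeCover(list(A.modules)[::-1])
        assert overlapping_nmi(A, B, U) == pytest.approx(overlapping_nmi(A2, B, U))

    def test_unrelated_random_cover_scores_low(self):
        rng = np.random.default_rng(1)
        U = [str(i) for i in range(200)]
        A = NodeCover([frozenset(U[i::4]) for i in range(4)])
        B = NodeCover(
            [frozenset(rng.choice(U, 50, replace=False)) for _ in range(4)]
        )
        assert overlapping_nmi(A, B, U) < 0.1

    def test_node_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlapping_nmi(NodeCover([{"z"}]), NodeCover([{"a"}]), ["a"])


class TestExtendedModularity:
    def test_whole_graph_single_module_is_zero(self, karate):
        cover = NodeCover([set(karate.node_labels)])
        assert extended_modularity(karate, cover) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_bridge_partition(self):
        net = Network.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"),
             ("c", "d")]
        )
        cover = NodeCover([{"a", "b", "c"}, {"d", "e", "f"}])
        assert extended_modularity(net, cover) == pytest.approx(5 / 14, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_standard_modularity_on_partitions(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g.remove_nodes_from([u for u in list(g) if g.degree(u) == 0])
        net = Network.from_networkx(g)
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=net.n_nodes)
        parts = {}
        for lab, grp in zip(net.node_labels, labels):
            parts.setdefault(grp, set()).add(lab)
        cover = NodeCover([frozenset(s) for s in parts.values()])
        by_label = {str(u): u for u in g.nodes}
        standard = nx.algorithms.community.modularity(
            g, [{by_label[u] for u in s} for s in parts.values()]
        )
        assert extended_modularity(net, cover) == pytest.approx(standard, abs=1e-9)

    def test_overlap_down_weighting_by_membership_counts(self):
        # node b sits in both modules: every pair involving b is damped by 1/2
        # (and the (b,b) self pair by 1/4), computed here directly
        net = Network.from_edges([("a", "b"), ("b", "c")])
        cover = NodeCover([{"a", "b"}, {"b", "c"}])
        W = net.dense()
        d = net.degrees
        two_m = d.sum()
        O = {"a": 1, "b": 2, "c": 1}
        idx = net.index_of
        expected = 0.0
        for mod in cover.modules:
            for u in mod:
                for v in mod:
                    expected += (
                        (W[idx(u), idx(v)] - d[idx(u)] * d[idx(v)] / two_m)
                        / (O[u] * O[v])
                    )
        expected /= two_m
        assert extended_modularity(net, cover) == pytest.approx(expected, abs=1e-12)


class TestEnrichment:
    def test_constant_similarity_is_one(self):
        cover = NodeCover([{"a", "b"}, {"c", "d"}])
        assert enrichment(cover, lambda u, v: 1.0, "abcd") == pytest.approx(1.0)

    def test_whole_network_community_is_one(self):
        U = list("abcde")
        cover = NodeCover([set(U)])
        rng = np.random.default_rng(0)
        sim = {frozenset((u, v)): float(rng.integers(0, 2)) for i, u in enumerate(U)
               for v in U[i + 1:]}
        if not any(sim.values()):
            sim[frozenset(("a", "b"))] = 1.0
        assert enrichment(cover, lambda u, v: sim[frozenset((u, v))], U) == pytest.approx(1.0)

    def test_hand_counted_ratio(self):
        U = list("abcdef")
        inside = {frozenset(p) for p in [("a", "b"), ("a", "c"), ("b", "c")]}
        cover = NodeCover([{"a", "b", "c"}])
        val = enrichment(cover, lambda u, v: 1.0 if frozenset((u, v)) in inside else 0.0, U)
        assert val == pytest.approx((3 / 3) / (3 / 15))

    def test_no_within_pairs_raises(self):
        with pytest.raises(ValueError):
            enrichment(NodeCover([{"a"}]), lambda u, v: 1.0, "abc")


class TestRescaleMDL:
    @pytest.mark.parametrize(
        "value,expected", [(4.0, 1.0), (9.0, 0.0), (6.5, 0.5), (10.0, -0.2)]
    )
    def test_linear_map(self, value, expected):
        assert rescale_mdl(value, optimal=4.0, baseline=9.0) == pytest.approx(expected)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            rescale_mdl(1.0, 2.0, 2.0)


class TestSampleSubnetwork:
    def _planted(self):
        net, _, cover = nlc.planted_hybrid_network(seed=0)
        return net, cover

    def test_deterministic_under_seed(self):
        net, cover = self._planted()
        a = sample_subnetwork(net, cover, seed=3)
        b = sample_subnetwork(net, cover, seed=3)
        assert a is not None and b is not None
        assert a[0].node_labels == b[0].node_labels

    def test_accepted_sample_has_structure(self):
        net, cover = self._planted()
        out = sample_subnetwork(net, cover, seed=1)
        assert out is not None
        sub, sub_cover = out
        assert extended_modularity(sub, sub_cover) >= 0.1
        assert set().union(*[set(m) for m in sub_cover.modules]) <= set(sub.node_labels)

    def test_all_small_communities_rejected(self, karate):
        gt = NodeCover([{"1", "2"}, {"3", "4"}, {"1", "2"}])
        with pytest.raises(ValueError):
            sample_subnetwork(karate, gt, seed=0)
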