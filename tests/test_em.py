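"""EM learner: initialization, E/M steps (with a numerical oracle), fitting."""

import numpy as np
import pytest
from scipy.optimize import minimize

import nlc
from nlc.em import e_step, fit_em, init_params, m_step
from nlc.model import DegreeModel, log_likelihood
from nlc.network import Network

from .conftest import random_connected_net


class TestInitParams:
    def test_c1_is_degrees(self, karate):
        model = init_params(karate, 1, rng=7)
        np.testing.assert_array_equal(model.D[:, 0], karate.degrees)

    def test_rows_sum_to_degrees(self, karate):
        model = init_params(karate, 4, rng=0)
        np.testing.assert_allclose(model.D.sum(axis=1), karate.degrees, atol=1e-12)

    def test_deterministic_under_seed(self, karate):
        a = init_params(karate, 3, rng=42).D
        b = init_params(karate, 3, rng=42).D
        np.testing.assert_array_equal(a, b)

    def test_invalid_c(self, karate):
        with pytest.raises(ValueError):
            init_params(karate, 0, rng=0)


class TestESteps:
    def test_c1_all_ones(self, karate):
        resp = e_step(karate, init_params(karate, 1, rng=0))
        np.testing.assert_array_equal(resp.q, np.ones((karate.n_edges, 1)))

    def test_zero_column_gets_zero_responsibility(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        model = DegreeModel(np.column_stack([net.degrees, np.zeros(3)]))
        resp = e_step(net, model)
        assert not resp.q[:, 1].any()

    def test_symmetric_communities_split_evenly(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        half = net.degrees / 2
        resp = e_step(net, DegreeModel(np.column_stack([half, half])))
        np.testing.assert_allclose(resp.q, 0.5)

    def test_rows_normalized(self, karate):
        resp = e_step(karate, init_params(karate, 5, rng=1))
        np.testing.assert_allclose(resp.q.sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_model_raises(self):
        net = Network.from_edges([("a", "b"), ("c", "d")])
        D = np.zeros((4, 1))
        D[:2, 0] = 1.0  # edge (c, d) inexplicable
        with pytest.raises(ValueError):
            e_step(net, DegreeModel(D))


class TestMStep:
    def test_path_split_responsibilities(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        from nlc.model import Responsibilities

        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        D = m_step(net, Responsibilities(q)).D
        b = net.index_of("b")
        assert D[b].tolist() == [1.0, 1.0]

    def test_row_sums_exact(self, karate):
        resp = e_step(karate, init_params(karate, 6, rng=2))
        model = m_step(karate, resp)
        np.testing.assert_allclose(model.D.sum(axis=1), karate.degrees, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_constrained_numerical_maximization(self, seed):
        """Closed-form M-step equals SLSQP maximization of the auxiliary
        function under the per-node degree constraints (4-node instances)."""
        net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        n, c = 4, 2
        model = init_params(net, c, rng=seed)
        resp = e_step(net, model)
        closed = m_step(net, resp).D
        q, d = resp.q, net.degrees

        def neg_aux(x):
            D = x.reshape(n, c)
            Dk = D.sum(axis=0)
            val = -Dk.sum()
            for e, (i, j, w) in enumerate(zip(net.edge_i, net.edge_j, net.edge_w)):
                mult = 1.0 if i == j else 2.0
                for k in range(c):
                    if q[e, k] > 0:
                        rate = D[i, k] * D[j, k] / Dk[k] if Dk[k] > 0 else 1e-300
                        val += mult * w * q[e, k] * np.log(max(rate, 1e-300))
            return -val

        cons = [
            {"type": "eq", "fun": (lambda x, i=i: x.reshape(n, c)[i].sum() - d[i])}
            for i in range(n)
        ]
        res = minimize(
            neg_aux,
            (closed + 0.1).ravel(),
            bounds=[(1e-9, None)] * (n * c),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        np.testing.assert_allclose(res.x.reshape(n, c), closed, atol=1e-6)


class TestFitEM:
    def test_two_triangles_block_recovery(self, two_triangles):
        model, _ = fit_em(two_triangles, 2, restarts=10, seed=0)
        D = model.D
        cols = D[:3].sum(axis=0).argsort()  # order columns by first-triangle mass
        first, second = D[:, cols[1]], D[:, cols[0]]
        np.testing.assert_allclose(first[:3], 2.0, atol=1e-6)
        np.testing.assert_allclose(second[3:], 2.0, atol=1e-6)
        np.testing.assert_allclose(first[3:], 0.0, atol=1e-6)

    def test_c1_immediately_converges_to_degrees(self, karate):
        model, trace = fit_em(karate, 1, restarts=3, seed=0)
        np.testing.assert_array_equal(model.D[:, 0], karate.degrees)

    def test_monotone_loglikelihood_trace(self):
        for seed in range(10):
            net = random_connected_net(seed)
            _, trace = fit_em(net, 3, restarts=2, max_iter=100, seed=seed)
            for lls in trace.objective:
                assert (np.diff(lls) >= -1e-10).all()

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            fit_em(Network(np.zeros((3, 3))), 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_best_restart_matches_constrained_optimizer(self, seed):
        """Best-of-restarts EM likelihood equals direct constrained
        maximization of the log-likelihood on a tiny graph (c=2)."""
        net = random_connected_net(seed, n=5, p=0.8)
        n = net.n_nodes
        model, _ = fit_em(net, 2, restarts=20, max_iter=2000, tol=1e-12, seed=seed)
        ll_em = log_likelihood(net, model)
        d = net.degrees

        def neg(x):
            D = np.empty((n, 2))
            t = 1 / (1 + np.exp(-np.clip(x, -500, 500)))  # degree fraction in community 1
            D[:, 0] = d * t
            D[:, 1] = d * (1 - t)
            return -log_likelihood(net, DegreeModel(np.maximum(D, 0)))

        best = np.inf
        for s in range(30):
            x0 = np.random.default_rng(1000 * seed + s).normal(size=n) * 3
            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
            best = min(best, res.fun)
        assert ll_em >= -best - 1e-6
        assert abs(ll_em - (-best)) < 1e-4 or ll_em > -best
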