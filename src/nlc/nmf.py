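"""Squared-loss fitting by constrained symmetric matrix factorization.

Writing ``X_ik = d_ik / sqrt(D_k)`` turns the expected-weight matrix into
``X X^T``, so the squared-loss fit of the model is a symmetric NMF problem
with the degree constraint ``X X^T 1 = d`` enforced by a quadratic penalty:

    O(X) = ||A - X X^T||_F^2 + lambda * ||X X^T 1 - d||^2 .

Gradient splitting gives a multiplicative update

    X <- X * (num / den)^eta,
    num = A X + (lambda/2) (d 1^T + 1 d^T) X,
    den = X X^T X + (lambda/2) ((X X^T 1) 1^T + 1 (X X^T 1)^T) X,

whose fixed points are exactly the KKT stationary points and along which O
is non-increasing (with exponent eta = 1/2; see docs/methods.md).
The fit runs a two-phase schedule: unconstrained (lambda = 0) to find a good
basin, then lambda = 1000 to drive the degree constraint home; parameters
are recovered by d_ik = X_ik * sum_j X_jk.
"""

from __future__ import annotations

import numpy as np

from .em import FitTrace
from .model import DegreeModel
from .network import Network

__all__ = [
    "FactorMatrix",
    "model_to_factor",
    "factor_to_model",
    "nmf_objective",
    "nmf_update",
    "fit_nmf",
]

# Multiplicative-update exponent.  eta = 1/2 keeps the objective
# non-increasing on symmetric factorizations of this form (verified by the
# property suite); eta = 1/4 is the more conservative damping if needed.
ETA = 0.5
X_FLOOR = 1e-12


class FactorMatrix:
    """Nonnegative n x c factor with X_ik = d_ik / sqrt(D_k)."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if (X < 0).any():
            raise ValueError("X must be nonnegative")
        self.X = X

    @property
    def shape(self):
        return self.X.shape


def model_to_factor(model: DegreeModel) -> FactorMatrix:
    """X_ik = d_ik / sqrt(D_k); empty communities map to zero columns."""
    Dk = model.community_degrees
    scale = np.where(Dk > 0, 1.0 / np.sqrt(np.where(Dk > 0, Dk, 1.0)), 0.0)
    return FactorMatrix(model.D * scale)


def factor_to_model(X: FactorMatrix | np.ndarray) -> DegreeModel:
    """Inverse map d_ik = X_ik * sum_j X_jk (since sqrt(D_k) = sum_j X_jk)."""
    Xa = X.X if isinstance(X, FactorMatrix) else np.asarray(X, dtype=float)
    return DegreeModel(Xa * Xa.sum(axis=0))


def nmf_objective(net: Network, X: FactorMatrix | np.ndarray, lam: float = 0.0) -> float:
    """O = ||A - X X^T||_F^2 + lam * ||X X^T 1 - d||^2."""
    Xa = X.X if isinstance(X, FactorMatrix) else np.asarray(X, dtype=float)
    A = net.dense()
    R = A - Xa @ Xa.T
    resid = float((R * R).sum())
    if lam:
        r = Xa @ (Xa.T @ np.ones(net.n_nodes)) - net.degrees
        resid += lam * float(r @ r)
    return resid


def _update(A: np.ndarray, d: np.ndarray, X: np.ndarray, lam: float, eta: float) -> np.ndarray:
    s = X.sum(axis=0)  # 1^T X
    XtX = X.T @ X
    Xs = X @ s  # X X^T 1
    num = A @ X + 0.5 * lam * (np.outer(d, s) + np.outer(np.ones(len(d)), d @ X))
    den = X @ XtX + 0.5 * lam * (np.outer(Xs, s) + np.outer(np.ones(len(d)), Xs @ X))
    den = np.maximum(den, X_FLOOR)
    ratio = np.maximum(num, 0.0) / den
    return np.maximum(X * ratio**eta, X_FLOOR)


def nmf_update(net: Network, X: FactorMatrix | np.ndarray, lam: float = 0.0, eta: float = ETA) -> FactorMatrix:
    """One multiplicative update; the objective is non-increasing."""
    Xa = X.X if isinstance(X, FactorMatrix) else np.asarray(X, dtype=float)
    Xa = np.maximum(Xa, X_FLOOR)
    return FactorMatrix(_update(net.dense(), net.degrees, Xa, lam, eta))


def fit_nmf(
    net: Network,
    c: int,
    restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-8,
    lam: float = 1000.0,
    seed: np.random.Generator | int | None = None,
    eta: float = ETA,
) -> tuple[DegreeModel, FitTrace]:
    """Two-phase penalized symmetric NMF fit, best of ``restarts``.

    Phase 1 minimizes the plain factorization loss (lambda = 0) from a random
    nonnegative start; phase 2 restarts from that solution with the degree
    penalty active (lambda = ``lam``).  Returns the model recovered from the
    factor with the lowest final phase-2 objective.
    """
    if c < 1:
        raise ValueError("need at least one community")
    if net.n_edges == 0:
        raise ValueError("cannot fit a network with no edges")
    rng = np.random.default_rng(seed)
    A = net.dense()
    d = net.degrees
    n = net.n_nodes
    scale = np.sqrt(max(A.mean(), X_FLOOR))
    best_obj = np.inf
    best_X: np.ndarray | None = None
    trace = FitTrace()
    for r in range(restarts):
        X = np.maximum(rng.random((n, c)) * scale, X_FLOOR)
        objs: list[float] = []
        for phase_lam in (0.0, lam):
            prev = nmf_objective(net, X, phase_lam)
            for _ in range(max_iter):
                X = _update(A, d, X, phase_lam, eta)
                obj = nmf_objective(net, X, phase_lam)
                objs.append(obj)
                if abs(prev - obj) <= tol * max(abs(prev), 1.0):
                    prev = obj
                    break
                prev = obj
        trace.objective.append(np.asarray(objs))
        final = nmf_objective(net, X, lam)
        if final < best_obj:
            best_obj = final
            best_X = X
            trace.best_restart = r
    assert best_X is not None
    # entries at the numerical floor are artifacts of the multiplicative rule
    best_X = np.where(best_X <= 2 * X_FLOOR, 0.0, best_X)
    return factor_to_model(best_X), trace
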