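"""Independent oracles used by the test suite.

These deliberately avoid the code paths under test: the SVM duals are
re-solved with a generic constrained QP solver (SLSQP), and the exact
Wilcoxon null distribution is obtained by brute-force enumeration of all
group assignments.
"""

import itertools

import numpy as np
from scipy import optimize


def qp_dual_max(Q, p, y, C):
    """Maximize p^T g - 1/2 g^T Q g subject to y^T g = 0, 0 <= g <= C.

    Generic solver (SLSQP) on the same dual the SMO implementation solves.
    Returns (gamma, objective).
    """
    n = len(p)

    def neg_obj(g):
        return 0.5 * g @ Q @ g - p @ g

    def neg_grad(g):
        return Q @ g - p

    best = None
    for ftol in (1e-14, 1e-12, 1e-10):
        for x0 in (np.zeros(n), np.full(n, min(C, 1.0) * 1e-3)):
            res = optimize.minimize(
                neg_obj,
                x0=x0,
                jac=neg_grad,
                bounds=[(0.0, C)] * n,
                constraints=[{"type": "eq", "fun": lambda g: y @ g, "jac": lambda g: y}],
                method="SLSQP",
                options={"ftol": ftol, "maxiter": 2000},
            )
            feasible = abs(y @ res.x) < 1e-8
            if feasible and (best is None or res.fun < best.fun):
                best = res
            if res.success and feasible:
                return res.x, -res.fun
    assert best is not None, "QP oracle failed on every attempt"
    return best.x, -best.fun


def qp_svc(X, t, C, kernel_scale=1.0):
    Xs = np.asarray(X, float) / kernel_scale
    t = np.asarray(t, float)
    K = Xs @ Xs.T
    Q = (t[:, None] * t[None, :]) * K
    gamma, obj = qp_dual_max(Q, np.ones(len(t)), t, C)
    w = (gamma * t) @ Xs
    return gamma, w, obj


def qp_svr(X, t, C, epsilon, kernel_scale=1.0):
    Xs = np.asarray(X, float) / kernel_scale
    t = np.asarray(t, float)
    n = len(t)
    K = Xs @ Xs.T
    y = np.concatenate([np.ones(n), -np.ones(n)])
    Q = (y[:, None] * y[None, :]) * np.tile(K, (2, 2))
    p = np.concatenate([t - epsilon, -t - epsilon])
    gamma, obj = qp_dual_max(Q, p, y, C)
    beta = gamma[:n] - gamma[n:]
    w = beta @ Xs
    return beta, w, obj


def wilcoxon_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all C(n, n_a) assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    w_obs = ranks[: len(a)].sum()
    n, n_a = len(pooled), len(a)
    sums = np.array(
        [sum(c) for c in itertools.combinations(range(1, n + 1), n_a)], dtype=float
    )
    p_low = np.mean(sums <= w_obs)
    p_high = np.mean(sums >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))
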