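"""Linear-kernel support vector machines solved by sequential minimal
optimization (SMO), for classification (L1-norm soft margin) and regression
(epsilon-insensitive L1 loss), plus grid-search hyperparameter selection
under nested k-fold cross-validation.

Both duals are instances of one canonical quadratic program

    min_gamma  1/2 gamma^T Q gamma - p^T gamma
    s.t.       y^T gamma = 0,   0 <= gamma_i <= C,

with Q_ij = y_i y_j k(x_i, x_j).  Classification uses gamma = alpha, y the
labels and p = 1.  epsilon-SVR is rewritten on 2N variables gamma =
(alpha, alpha*) with y = (+1, ..., -1, ...) and p = (t - eps, -t - eps).
The solver performs maximal-KKT-violating-pair coordinate ascent and
terminates when the violation m - M drops below ``tol``.

The linear kernel carries a scale: k(x, x') = <x/s, x'/s>.  The primal
weight vector lives in the scaled feature space, so decision values are
<w, x/s> + b and doubling the scale is exactly equivalent to halving every
coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SVMSolution",
    "SMONonConvergence",
    "GridSearchResult",
    "train_svc",
    "train_svr",
    "decision_value",
    "classify",
    "grid_search_nested_cv",
    "max_kkt_violation",
    "dual_objective",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 100_000


class SMONonConvergence(RuntimeError):
    """SMO failed to reach the KKT tolerance within the iteration cap."""


@dataclass
class SVMSolution:
    """A trained SVM in component space.

    ``alphas`` holds the dual coefficients per training point: alpha_n in
    [0, C] for classification, the signed difference beta_n = alpha_n -
    alpha_n* in [-C, C] for regression.  ``w`` is the primal weight vector in
    the scaled feature space, so ``w = sum_n alphas_n t_n x_n / s``
    (classification) or ``sum_n alphas_n x_n / s`` (regression).
    """

    mode: str
    w: np.ndarray
    b: float
    alphas: np.ndarray
    C: float
    kernel_scale: float
    epsilon: float | None = None
    dual_objective_: float = 0.0
    kkt_violation_: float = 0.0
    n_iter_: int = 0
    X_train: np.ndarray | None = None
    t_train: np.ndarray | None = None

    @property
    def support_(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.alphas) > 1e-12 * max(self.C, 1.0))


def _smo(Q, p, y, C, tol, max_iter):
    """Generic SMO on the canonical dual.  Returns (gamma, b, iters, viol)."""
    n = p.shape[0]
    gamma = np.zeros(n)
    grad = -p.copy()  # grad_i = (Q gamma)_i - p_i
    lo_eps = 1e-12 * max(C, 1.0)
    it = 0
    m = M = 0.0
    for it in range(1, max_iter + 1):
        yG = -(y * grad)
        at_lo = gamma <= lo_eps
        at_hi = gamma >= C - lo_eps
        up = ~((at_hi & (y > 0)) | (at_lo & (y < 0)))
        low = ~((at_hi & (y < 0)) | (at_lo & (y > 0)))
        if not up.any() or not low.any():  # pragma: no cover - degenerate box
            m = M = 0.0
            break
        i = int(np.flatnonzero(up)[np.argmax(yG[up])])
        j = int(np.flatnonzero(low)[np.argmin(yG[low])])
        m, M = float(yG[i]), float(yG[j])
        if m - M < tol:
            break
        a = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        a = max(a, 1e-12)
        delta = (m - M) / a
        # feasible step sizes along (y_i e_i - y_j e_j)
        cap_i = (C - gamma[i]) if y[i] > 0 else gamma[i]
        cap_j = (C - gamma[j]) if y[j] < 0 else gamma[j]
        delta = min(delta, cap_i, cap_j)
        if delta <= 0:  # pragma: no cover - numerical corner
            break
        gamma[i] += y[i] * delta
        gamma[j] -= y[j] * delta
        gamma[i] = min(max(gamma[i], 0.0), C)
        gamma[j] = min(max(gamma[j], 0.0), C)
        grad += delta * (y[i] * Q[:, i] - y[j] * Q[:, j])
        if it % 1000 == 0:
            logger.debug("SMO iter %d: KKT violation %.3e", it, m - M)
    else:
        raise SMONonConvergence(
            f"SMO did not converge in {max_iter} iterations "
            f"(KKT violation {m - M:.3e}, tol {tol:.3e})"
        )
    # bias: average -y_i grad_i over free points, else midpoint of [M, m]
    free = (gamma > lo_eps) & (gamma < C - lo_eps)
    yG = -(y * grad)
    if free.any():
        b = float(yG[free].mean())
    else:
        b = 0.5 * (m + M)
    viol = max(m - M, 0.0)
    return gamma, b, it, viol


def _check_hyper(C: float, kernel_scale: float) -> None:
    if C <= 0:
        raise ValueError("C must be positive")
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be positive")


def train_svc(
    features: np.ndarray,
    labels: np.ndarray,
    C: float,
    kernel_scale: float = 1.0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SVMSolution:
    """Train an L1-soft-margin linear SVM classifier via SMO."""
    _check_hyper(C, kernel_scale)
    X = np.asarray(features, dtype=float)
    t = np.asarray(labels, dtype=float)
    if X.ndim != 2 or t.shape != (X.shape[0],):
        raise ValueError("features must be N x K with one label per row")
    if not (np.all(np.abs(t) == 1.0)):
        raise ValueError("labels must be +/-1")
    if np.unique(t).size < 2:
        raise ValueError("training set contains a single class")
    Xs = X / kernel_scale
    K = Xs @ Xs.T
    Q = (t[:, None] * t[None, :]) * K
    p = np.ones(X.shape[0])
    gamma, b, it, viol = _smo(Q, p, t, C, tol, max_iter)
    w = (gamma * t) @ Xs
    obj = float(p @ gamma - 0.5 * gamma @ Q @ gamma)
    return SVMSolution(
        mode="classify",
        w=w,
        b=b,
        alphas=gamma,
        C=C,
        kernel_scale=kernel_scale,
        dual_objective_=obj,
        kkt_violation_=viol,
        n_iter_=it,
        X_train=X,
        t_train=t,
    )


def train_svr(
    features: np.ndarray,
    targets: np.ndarray,
    C: float,
    epsilon: float | None = None,
    kernel_scale: float = 1.0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SVMSolution:
    """Train an epsilon-insensitive (L1-loss) linear SVR via SMO.

    When ``epsilon`` is None it defaults to 0.1 times the target standard
    deviation.  Points strictly inside the epsilon tube receive zero dual
    coefficient.
    """
    _check_hyper(C, kernel_scale)
    X = np.asarray(features, dtype=float)
    t = np.asarray(targets, dtype=float)
    if X.ndim != 2 or t.shape != (X.shape[0],):
        raise ValueError("features must be N x K with one target per row")
    if epsilon is None:
        epsilon = 0.1 * float(t.std())
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    n = X.shape[0]
    Xs = X / kernel_scale
    K = Xs @ Xs.T
    y2 = np.concatenate([np.ones(n), -np.ones(n)])
    K2 = np.tile(K, (2, 2))
    Q = (y2[:, None] * y2[None, :]) * K2
    p = np.concatenate([t - epsilon, -t - epsilon])
    gamma, b, it, viol = _smo(Q, p, y2, C, tol, max_iter)
    beta = gamma[:n] - gamma[n:]
    w = beta @ Xs
    obj = float(p @ gamma - 0.5 * gamma @ Q @ gamma)
    if not np.any(np.abs(beta) > 1e-12 * max(C, 1.0)):
        # degenerate tube: any b with all residuals inside is optimal;
        # take the midrange, the centre of the feasible interval
        b = 0.5 * (float(t.max()) - epsilon + float(t.min()) + epsilon)
    return SVMSolution(
        mode="regress",
        w=w,
        b=b,
        alphas=beta,
        C=C,
        kernel_scale=kernel_scale,
        epsilon=epsilon,
        dual_objective_=obj,
        kkt_violation_=viol,
        n_iter_=it,
        X_train=X,
        t_train=t,
    )


def decision_value(model: SVMSolution, coords: np.ndarray) -> np.ndarray | float:
    """Continuous output score <w, coords/s> + b."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] != model.w.shape[0]:
        raise ValueError(
            f"dimension mismatch: coords have {coords.shape[-1]} features, model {model.w.shape[0]}"
        )
    score = coords @ model.w / model.kernel_scale + model.b
    return float(score) if score.ndim == 0 else score


def classify(model: SVMSolution, coords: np.ndarray) -> np.ndarray | int:
    """Hard label sign(score); a score of exactly 0 maps to +1."""
    score = decision_value(model, coords)
    lab = np.where(np.asarray(score) >= 0, 1, -1)
    return int(lab) if lab.ndim == 0 else lab


def dual_objective(model: SVMSolution) -> float:
    """The maximized dual objective value reached by the solver."""
    return model.dual_objective_


def max_kkt_violation(model: SVMSolution) -> float:
    """Recompute the maximal KKT violation m - M from the stored duals."""
    X = model.X_train / model.kernel_scale
    K = X @ X.T
    if model.mode == "classify":
        t = model.t_train
        Q = (t[:, None] * t[None, :]) * K
        p = np.ones(len(t))
        y = t
        gamma = model.alphas
    else:
        n = len(model.t_train)
        y = np.concatenate([np.ones(n), -np.ones(n)])
        Q = (y[:, None] * y[None, :]) * np.tile(K, (2, 2))
        p = np.concatenate([model.t_train - model.epsilon, -model.t_train - model.epsilon])
        beta = model.alphas
        gamma = np.concatenate([np.clip(beta, 0, None), np.clip(-beta, 0, None)])
    grad = Q @ gamma - p
    yG = -(y * grad)
    lo_eps = 1e-12 * max(model.C, 1.0)
    up = ~((gamma >= model.C - lo_eps) & (y > 0)) & ~((gamma <= lo_eps) & (y < 0))
    low = ~((gamma >= model.C - lo_eps) & (y < 0)) & ~((gamma <= lo_eps) & (y > 0))
    if not up.any() or not low.any():
        return 0.0
    return float(yG[up].max() - yG[low].min())


# ---------------------------------------------------------------------------
# cross-validated grid search


@dataclass
class GridSearchResult:
    C: float
    kernel_scale: float
    epsilon: float | None
    cv_loss: float
    table: pd.DataFrame = field(repr=False, default=None)


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator):
    folds = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"fold count {k} exceeds class size {len(idx)} for class {cls}"
            )
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def _plain_folds(n: int, k: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(idx, k)]


def grid_search_nested_cv(
    features: np.ndarray,
    targets: np.ndarray,
    C_grid,
    scale_grid,
    k: int = 10,
    seed: int = 0,
    mode: str = "classify",
    epsilon_grid=None,
    tol: float = DEFAULT_TOL,
) -> GridSearchResult:
    """Select (C, kernel_scale[, epsilon]) by k-fold cross-validated loss.

    Classification uses stratified folds and misclassification rate;
    regression uses plain folds and mean absolute error.  Fold assignment is
    seeded.  Ties are broken toward smaller C, then smaller kernel scale,
    then smaller epsilon.
    """
    X = np.asarray(features, dtype=float)
    t = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"fold count {k} exceeds sample size {n}")
    rng = np.random.default_rng(seed)
    if mode == "classify":
        folds = _stratified_folds(t, k, rng)
    elif mode == "regress":
        folds = _plain_folds(n, k, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    eps_values = [None] if epsilon_grid is None else sorted(epsilon_grid)
    records = []
    best = None
    for C in sorted(C_grid):
        for s in sorted(scale_grid):
            for eps in eps_values:
                losses = []
                for val_idx in folds:
                    tr = np.setdiff1d(np.arange(n), val_idx)
                    if mode == "classify":
                        m = train_svc(X[tr], t[tr], C, s, tol=tol)
                        pred = classify(m, X[val_idx])
                        losses.append(float(np.mean(pred != t[val_idx])))
                    else:
                        m = train_svr(X[tr], t[tr], C, epsilon=eps, kernel_scale=s, tol=tol)
                        pred = decision_value(m, X[val_idx])
                        losses.append(float(np.mean(np.abs(pred - t[val_idx]))))
                loss = float(np.mean(losses))
                records.append({"C": C, "kernel_scale": s, "epsilon": eps, "cv_loss": loss})
                if best is None or loss < best["cv_loss"]:
                    best = records[-1]
    table = pd.DataFrame(records)
    return GridSearchResult(
        C=best["C"],
        kernel_scale=best["kernel_scale"],
        epsilon=best["epsilon"],
        cv_loss=best["cv_loss"],
        table=table,
    )
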