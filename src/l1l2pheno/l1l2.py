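"""Naive elastic net with regularized-least-squares weight correction.

The estimator minimizes

    (1/n) * ||y - X w||^2  +  mu * ||w||^2  +  tau * ||w||_1

by proximal gradient descent (iterative soft-thresholding, optionally with
Nesterov acceleration).  The l1 term drives exact sparsity; the l2 term
stabilizes the solution under correlated predictors, letting groups of
linked SNPs enter together.  The naive minimizer selects the right features
but with shrunken weights, so a second step refits a ridge regression
restricted to the selected support:

    w_tilde = (X_S^T X_S + lam * n * I)^{-1} X_S^T y

Columns are standardized to zero mean / unit variance and y is centered
before solving; the intercept is restored so predictions live on the
original trait scale.  Weights and rankings are reported on the
standardized scale, where magnitudes are comparable across SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "L1L2Hyperparams",
    "SolverSettings",
    "L1L2Model",
    "soft_threshold",
    "fit_naive_elastic_net",
    "select_support",
    "rls_debias",
    "fit_l1l2",
    "predict",
    "rank_features",
    "elastic_net_objective",
]


@dataclass(frozen=True, order=True)
class L1L2Hyperparams:
    """Penalty triple: mu (l2 of the selection step), tau (l1), lam (RLS ridge)."""

    mu: float
    tau: float
    lam: float

    def __post_init__(self) -> None:
        if self.mu < 0 or self.tau < 0 or self.lam < 0:
            raise ValueError("hyperparameters must be nonnegative")


@dataclass(frozen=True)
class SolverSettings:
    """Proximal-gradient controls.

    tolerance: stop when the relative l2 change of w falls below this.
    step_size: "auto" uses 1/L with L the Lipschitz constant of the smooth
    part, estimated by power iteration.  accelerate enables FISTA momentum.
    """

    tolerance: float = 1e-6
    max_iterations: int = 10_000
    step_size: float | str = "auto"
    accelerate: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class L1L2Model:
    hyperparams: L1L2Hyperparams
    weights: np.ndarray            # debiased, standardized scale, zero off support
    naive_weights: np.ndarray      # raw elastic-net minimizer (standardized scale)
    support: np.ndarray            # sorted indices of nonzero naive weights
    intercept: float               # mean of y (training scale)
    feature_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    iterations: int = 0
    converged: bool = True

    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "hyperparams": {"mu": self.hyperparams.mu, "tau": self.hyperparams.tau,
                            "lam": self.hyperparams.lam},
            "support": [self.feature_names[j] for j in self.support],
            "weights_on_support": self.weights[self.support].tolist(),
            "intercept": self.intercept,
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "L1L2Model":
        d = json.loads(text)
        names = d["feature_names"]
        p = len(names)
        weights = np.zeros(p)
        support = np.array(sorted(names.index(nm) for nm in d["support"]), dtype=int)
        by_name = dict(zip(d["support"], d["weights_on_support"]))
        for j in support:
            weights[j] = by_name[names[j]]
        return cls(
            hyperparams=L1L2Hyperparams(**d["hyperparams"]),
            weights=weights,
            naive_weights=weights.copy(),
            support=support,
            intercept=d["intercept"],
            feature_names=names,
            x_mean=np.asarray(d["x_mean"]),
            x_scale=np.asarray(d["x_scale"]),
            iterations=d["iterations"],
            converged=d["converged"],
        )


def soft_threshold(v, t):
    """sign(v) * max(|v| - t, 0), elementwise."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be nonnegative")
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def elastic_net_objective(X, y, w, mu: float, tau: float) -> float:
    n = X.shape[0]
    r = y - X @ w
    return float(r @ r / n + mu * (w @ w) + tau * np.abs(w).sum())


def _lipschitz(X, mu: float, n_iter: int = 50, tol: float = 1e-7) -> float:
    """Largest eigenvalue of (2/n) X^T X + 2 mu I via power iteration."""
    n, p = X.shape
    rng = np.random.default_rng(0)
    v = rng.standard_normal(p)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        u = X.T @ (X @ v)
        nrm = np.linalg.norm(u)
        if nrm == 0:
            break
        new = nrm
        u /= nrm
        if abs(new - lam) < tol * max(new, 1.0):
            v = u
            lam = new
            break
        v, lam = u, new
    return 2.0 * lam / n + 2.0 * mu


def fit_naive_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    h: L1L2Hyperparams,
    s: SolverSettings = SolverSettings(),
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Minimize (1/n)||y - Xw||^2 + mu||w||^2 + tau||w||_1 by ISTA/FISTA.

    X is expected column-standardized and y centered.  Returns
    (weights, iterations, converged); hitting max_iterations sets
    converged=False without raising.  Warm starts via ``w0`` are exact:
    the fixed point does not depend on the start.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")

    L = _lipschitz(X, h.mu) if s.step_size == "auto" else 1.0 / float(s.step_size)
    if L <= 0:  # X identically zero and mu = 0
        return np.zeros(p), 0, True
    step = 1.0 / L
    # prox of step * tau * ||.||_1 applied after a gradient step on the
    # smooth part, whose gradient is (2/n) X^T (Xw - y) + 2 mu w
    thr = step * h.tau
    Xty = X.T @ y

    w = np.zeros(p) if w0 is None else np.asarray(w0, dtype=float).copy()
    z = w.copy()
    t_mom = 1.0
    converged = False
    it = 0
    for it in range(1, s.max_iterations + 1):
        grad = (2.0 / n) * (X.T @ (X @ z) - Xty) + 2.0 * h.mu * z
        w_new = soft_threshold(z - step * grad, thr)
        dw = np.linalg.norm(w_new - w)
        denom = max(np.linalg.norm(w_new), 1e-12)
        if s.accelerate:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            z = w_new + ((t_mom - 1.0) / t_new) * (w_new - w)
            t_mom = t_new
        else:
            z = w_new
        w = w_new
        if dw <= s.tolerance * denom or (dw == 0.0 and denom <= 1e-12):
            converged = True
            break
    return w, it, converged


def select_support(w: np.ndarray, zero_tol: float = 0.0) -> np.ndarray:
    """Indices with |w_j| > zero_tol (the thresholding solver is exactly sparse)."""
    return np.flatnonzero(np.abs(w) > zero_tol)


def rls_debias(X_sub: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge refit on the selected support: (X^T X + lam n I)^{-1} X^T y.

    lam = 0 falls back to least squares (pseudo-inverse if singular).
    An empty support returns an empty vector; the caller records a
    degenerate mean-predicting model.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    if X_sub.ndim != 2:
        raise ValueError("X_sub must be 2-D")
    n, k = X_sub.shape
    if k == 0:
        return np.zeros(0)
    A = X_sub.T @ X_sub + lam * n * np.eye(k)
    b = X_sub.T @ y
    if lam > 0:
        return scipy.linalg.solve(A, b, assume_a="pos")
    return scipy.linalg.lstsq(A, b)[0]


def _standardize(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def fit_l1l2(
    X: np.ndarray,
    y: np.ndarray,
    h: L1L2Hyperparams,
    s: SolverSettings = SolverSettings(),
    feature_names: list[str] | None = None,
    w0: np.ndarray | None = None,
) -> L1L2Model:
    """Full estimator: standardize, solve the elastic net, debias on support.

    Accepts raw (unstandardized) X and y; standardization statistics are
    stored on the model and re-applied at prediction time.  ``w0`` warm
    starts the selection step (standardized scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length differs from columns")
    Xs, x_mean, x_scale = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    w_naive, iters, conv = fit_naive_elastic_net(Xs, yc, h, s, w0=w0)
    support = select_support(w_naive)
    weights = np.zeros(p)
    if support.size:
        weights[support] = rls_debias(Xs[:, support], yc, h.lam)
    return L1L2Model(
        hyperparams=h,
        weights=weights,
        naive_weights=w_naive,
        support=support,
        intercept=y_mean,
        feature_names=list(feature_names),
        x_mean=x_mean,
        x_scale=x_scale,
        iterations=iters,
        converged=conv,
    )


def predict(m: L1L2Model, X_new: np.ndarray) -> np.ndarray:
    """Predicted phenotype on the original trait scale."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != m.weights.size:
        raise ValueError(
            f"expected {m.weights.size} columns, got {X_new.shape[1] if X_new.ndim == 2 else 'non-2D'}"
        )
    Xs = (X_new - m.x_mean) / m.x_scale
    return Xs @ m.weights + m.intercept


def rank_features(m: L1L2Model) -> "RankedList":
    """Partial ranked list of on-support features by decreasing |debiased weight|.

    Equal magnitudes break ties lexicographically by feature name, so the
    ranking is deterministic.
    """
    from .stability import RankedList

    items = [(float(-abs(m.weights[j])), m.feature_names[j]) for j in m.support]
    items.sort()
    return RankedList(items=[nm for _, nm in items], universe=list(m.feature_names))
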