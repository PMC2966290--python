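"""Independent oracles used by the test suite.

These deliberately avoid the package's solver paths: the elastic-net oracle
enumerates supports and solves each restricted problem from its stationarity
conditions; the Canberra oracle is a literal double loop.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plain normal-equations least squares."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def elastic_net_objective(X, y, w, mu, tau):
    n = X.shape[0]
    r = y - X @ w
    return float(r @ r / n + mu * (w @ w) + tau * np.abs(w).sum())


def _restricted_minimum(X, y, support, mu, tau, max_rounds=60):
    """Exact minimizer of the elastic-net objective restricted to a support.

    On a fixed support with fixed signs s the stationarity condition is
    (X_S^T X_S / n + mu I) w = X_S^T y / n - (tau/2) s; iterate the sign
    fixed point from the ridge solution.  Returns (w_full, ok); ok=False
    when the sign iteration cycles without a consistent solution (the
    restricted minimum then has a zero coordinate and is covered by a
    smaller support).
    """
    n, p = X.shape
    S = list(support)
    if not S:
        return np.zeros(p), True
    XS = X[:, S]
    A = XS.T @ XS / n + mu * np.eye(len(S))
    b = XS.T @ y / n
    s = np.sign(np.linalg.lstsq(A, b, rcond=None)[0])
    s[s == 0] = 1.0
    seen = set()
    for _ in range(max_rounds):
        w = np.linalg.solve(A, b - 0.5 * tau * s)
        new_s = np.sign(w)
        if np.all(new_s == s):
            full = np.zeros(p)
            full[S] = w
            return full, True
        key = tuple(new_s)
        if key in seen:
            return np.zeros(p), False
        seen.add(key)
        s = new_s
        s[s == 0] = 1.0
    return np.zeros(p), False


def exhaustive_elastic_net(X, y, mu, tau):
    """Global elastic-net minimizer by enumeration over all 2^p supports.

    Returns (w_star, objective).  Feasible only for small p (tests use
    p <= 12).
    """
    n, p = X.shape
    best_w = np.zeros(p)
    best_obj = elastic_net_objective(X, y, best_w, mu, tau)
    idx = list(range(p))
    for k in range(1, p + 1):
        for support in combinations(idx, k):
            w, ok = _restricted_minimum(X, y, support, mu, tau)
            if not ok:
                continue
            obj = elastic_net_objective(X, y, w, mu, tau)
            if obj < best_obj - 1e-15:
                best_obj = obj
                best_w = w
    return best_w, best_obj


def canberra_bruteforce(a, b) -> float:
    """Literal elementwise sum, no vectorization."""
    assert len(a) == len(b)
    total = 0.0
    for x, z in zip(a, b):
        total += abs(x - z) / (x + z)
    return total


def completed_ranks_bruteforce(items, universe):
    """Rank vector for a partial list, unlisted items at the mean free rank."""
    p = len(universe)
    k = len(items)
    fill = sum(range(k + 1, p + 1)) / max(p - k, 1)
    ranks = []
    for f in universe:
        ranks.append(items.index(f) + 1 if f in items else fill)
    return ranks
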