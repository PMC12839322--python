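"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package (and of the
higher-level scipy/statsmodels helpers the package calls): ranks are
computed by explicit sorting with tie averaging, OLS by normal equations,
and Benjamini-Hochberg by searching for the smallest level at which the
step-up procedure rejects.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) via explicit sorting with tie averaging."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_brute(x, y) -> tuple[float, float]:
    """Spearman rho as the Pearson correlation of average ranks; p from the
    t-approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    n = len(rx)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


def ols_brute(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(r2, adj_r2, model_p) by normal equations; X must be full rank."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    p = float(stats.f.sf(f, k, n - k - 1))
    return r2, adj, p


def _bh_rejections(p: np.ndarray, q: float) -> np.ndarray:
    """Step-up rejection set at level q."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        # tiny slack so q-candidates equal to m*p/j are not lost to
        # floating-point rounding
        if p[idx] <= rank * q / m + 1e-12:
            k_star = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


def bh_brute(p) -> np.ndarray:
    """Adjusted p_i = smallest level q at which the step-up procedure
    rejects hypothesis i (searched over the finite set of candidate
    levels m*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    sorted_p = np.sort(p)
    candidates = sorted(
        {min(1.0, m * sp / j) for j, sp in enumerate(sorted_p, start=1)}
    )
    adj = np.ones(m)
    for q in reversed(candidates):
        rejected = _bh_rejections(p, q)
        adj[rejected] = q
    return adj
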