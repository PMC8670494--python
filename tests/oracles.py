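"""Independent brute-force oracles used to check the implementations.

Each oracle is deliberately naive (enumeration, projected gradient, direct
matrix algebra) and shares no code with the package paths it validates.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_1nn(X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray) -> np.ndarray:
    """Nearest-neighbour regression by exhaustive Euclidean search."""
    out = np.empty(len(X_query))
    for i, q in enumerate(X_query):
        dists = np.sqrt(((X_train - q) ** 2).sum(axis=1))
        out[i] = y_train[np.argmin(dists)]
    return out


def projected_gradient_nnls(
    P: np.ndarray, y: np.ndarray, n_iter: int = 100_000
) -> np.ndarray:
    """NNLS by projected gradient descent with a fixed step size."""
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    lipschitz = np.linalg.norm(P.T @ P, 2)
    step = 1.0 / max(lipschitz, 1e-12)
    w = np.zeros(P.shape[1])
    for _ in range(n_iter):
        grad = P.T @ (P @ w - y)
        w = np.clip(w - step * grad, 0.0, None)
    return w


def ridge_normal_equations(P: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Ridge with intercept via the augmented normal equations, solved directly."""
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = P.mean(axis=0)
    ym = y.mean()
    A = P - mu
    b = y - ym
    w = np.linalg.inv(A.T @ A + lam * np.eye(P.shape[1])) @ (A.T @ b)
    return w, float(ym - mu @ w)


def exact_sign_test_p(n_pos: int, n_neg: int) -> float:
    """Two-sided exact sign test by direct binomial enumeration.

    Sums the probability of every outcome at most as likely as the observed
    one under Binomial(n, 1/2).
    """
    n = n_pos + n_neg
    if n == 0:
        return 1.0
    pmf = np.array([comb(n, k) for k in range(n + 1)], dtype=float) / 2.0**n
    return float(min(1.0, pmf[pmf <= pmf[n_pos] * (1 + 1e-12)].sum()))


def exact_wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p by full 2^n sign enumeration.

    Zeros discarded, tied |d| get average ranks; every sign assignment is
    enumerated explicitly, so only feasible for small n.
    """
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    nonzero = diffs[diffs != 0]
    n = len(nonzero)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(nonzero))
    w_obs = ranks[nonzero > 0].sum()
    w_all = np.array(
        [
            np.dot(ranks, signs)
            for signs in itertools.product((0.0, 1.0), repeat=n)
        ]
    )
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def average_linkage_merge(points: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive average-linkage agglomeration over row vectors (euclidean)."""
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dists = [
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            ]
            d = float(np.mean(dists))
            if best is None or d < best[2]:
                best = (a, b, d)
        a, b, d = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
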