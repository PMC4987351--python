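"""Independent brute-force oracles used across the test suite.

Everything here deliberately avoids the implementation paths under test:
distances via Floyd-Warshall, shortest-path counts via dynamic programming
over distance shells, spanning trees by exhaustive enumeration, regression
by explicit normal equations, ICC by explicit sums of squares.
"""

from __future__ import annotations

import itertools

import numpy as np


def fw_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by Floyd-Warshall."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d


def path_counts(adj: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[j, k] = number of shortest j-k paths (DP over distance)."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    for j in range(n):
        order = np.argsort(d[j])
        for k in order:
            if k == j or not np.isfinite(d[j, k]):
                continue
            preds = [m for m in range(n)
                     if adj[m, k] and d[j, m] == d[j, k] - 1]
            sigma[j, k] = sum(sigma[j, m] for m in preds)
    return sigma


def bf_degree(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(float)


def bf_global_efficiency(adj: np.ndarray) -> np.ndarray:
    d = fw_distances(adj)
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = fw_distances(adj)
    sigma = path_counts(adj, d)
    b = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or sigma[j, k] == 0:
                    continue
                if d[j, i] + d[i, k] == d[j, k]:
                    b[i] += sigma[j, i] * sigma[i, k] / sigma[j, k]
    return b


def bf_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        m = nbrs.size
        if m < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = fw_distances(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        out[i] = inv.sum() / (m * (m - 1))
    return out


def bf_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        deg = adj[i].sum()
        if deg < 2:
            continue
        tri = 0
        nbrs = np.flatnonzero(adj[i])
        for a, b in itertools.combinations(nbrs, 2):
            tri += adj[a, b]
        out[i] = 2.0 * tri / (deg * (deg - 1))
    return out


def random_connected_adjacency(n: int, p: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi adjacency, resampled until connected."""
    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1)
        adj = (adj | adj.T).astype(int)
        d = fw_distances(adj)
        if np.isfinite(d).all():
            return adj


def best_spanning_tree_weight(absmat: np.ndarray) -> float:
    """Maximum total |r| over all spanning trees, by exhaustive search."""
    n = absmat.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = -np.inf
    for combo in itertools.combinations(pairs, n - 1):
        adj = np.zeros((n, n), dtype=int)
        for i, j in combo:
            adj[i, j] = adj[j, i] = 1
        if np.isfinite(fw_distances(adj)).all():
            w = sum(absmat[i, j] for i, j in combo)
            best = max(best, w)
    return best


def normal_equations_residual(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual via explicit (X'X)^-1 X'y."""
    beta = np.linalg.inv(design.T @ design) @ design.T @ y
    return y - design @ beta


def anova_icc(values: np.ndarray) -> tuple[float, float, float]:
    """(icc, msb, msw) from explicit one-way ANOVA sums of squares."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssb = 0.0
    ssw = 0.0
    for i in range(n):
        mi = x[i].sum() / k
        ssb += k * (mi - grand) ** 2
        for j in range(k):
            ssw += (x[i, j] - mi) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw), msb, msw
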