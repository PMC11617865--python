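"""Independent brute-force oracles for graph metrics and statistics.

Deliberately naive implementations (triple-loop Floyd–Warshall, geodesic
counting by dynamic programming over distances, direct Pearson formula) used
only to verify the package's optimised kernels on small graphs.
"""

from __future__ import annotations

import math

import numpy as np


def fw_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by Floyd–Warshall."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def lp_oracle(adj: np.ndarray) -> float:
    d = fw_distances(adj)
    vals = [d[i, j] for i in range(len(adj)) for j in range(len(adj))
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def eglob_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = fw_distances(adj)
    acc = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
              if i != j and np.isfinite(d[i, j]))
    return acc / (n * (n - 1))


def nodal_eff_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = fw_distances(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n)
                     if j != i and np.isfinite(d[i, j])) / (n - 1)
    return out


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for x, a in enumerate(nbrs) for b in nbrs[x + 1:])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def local_eff_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = eglob_oracle(sub)
    return out


def geodesic_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances and numbers of geodesics per ordered pair, by DP over hops."""
    n = adj.shape[0]
    d = fw_distances(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        reach = sorted((d[s, t], t) for t in range(n) if np.isfinite(d[s, t]))
        for dist, t in reach:
            if t == s:
                continue
            sigma[s, t] = sum(sigma[s, v] for v in range(n)
                              if adj[v, t] and d[s, v] == dist - 1)
    return d, sigma


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness over unordered pairs, endpoints excluded."""
    n = adj.shape[0]
    d, sigma = geodesic_counts(adj)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    out[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return out


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(np.uint8)
    return adj
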