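"""Numba kernels for binary-graph metrics and degree-preserving rewiring.

These are the hot inner loops of the permutation engine: each permutation
replicate re-thresholds two pseudo-group matrices across the sparsity grid
and, for the normalised indices, rewires every graph into a null ensemble.
All kernels take dense uint8 adjacency matrices (symmetric, zero diagonal)
and are compiled with ``cache=True`` so the cost is paid once per machine.

Distances are unweighted breadth-first-search hop counts; unreachable pairs
are ``inf``. Randomness comes from numba's own global NumPy-compatible
generator, seeded explicitly by every stochastic kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "clustering_nodal_k",
    "distances_k",
    "cp_lp_eglob_k",
    "betweenness_k",
    "nodal_efficiency_k",
    "local_efficiency_k",
    "rewire_k",
    "null_cp_lp_k",
    "edges_of",
]


@njit(cache=True)
def clustering_nodal_k(adj):
    n = adj.shape[0]
    c = np.zeros(n)
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        t = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    t += 1
        c[i] = 2.0 * t / (k * (k - 1))
    return c


@njit(cache=True)
def distances_k(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        head = 0
        tail = 1
        queue[0] = s
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def cp_lp_eglob_k(adj):
    """Mean clustering, characteristic path length over finite pairs, and
    global efficiency (1/inf treated as 0). Lp is NaN for an edgeless graph."""
    n = adj.shape[0]
    cp = clustering_nodal_k(adj).mean()
    dist = distances_k(adj)
    lp_sum = 0.0
    lp_cnt = 0
    eff = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = dist[i, j]
            if d != np.inf:
                lp_sum += d
                lp_cnt += 1
                eff += 1.0 / d
    lp = lp_sum / lp_cnt if lp_cnt > 0 else np.nan
    eglob = eff / (n * (n - 1)) if n > 1 else 0.0
    return cp, lp, eglob


@njit(cache=True)
def betweenness_k(adj):
    """Brandes betweenness, unnormalised, endpoints excluded, unordered pairs."""
    n = adj.shape[0]
    bc = np.zeros(n)
    sigma = np.zeros(n)
    dist = np.empty(n, np.int64)
    delta = np.zeros(n)
    order = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for s in range(n):
        for i in range(n):
            sigma[i] = 0.0
            dist[i] = -1
            delta[i] = 0.0
        sigma[s] = 1.0
        dist[s] = 0
        head = 0
        tail = 1
        queue[0] = s
        cnt = 0
        while head < tail:
            v = queue[head]
            head += 1
            order[cnt] = v
            cnt += 1
            for w in range(n):
                if adj[v, w]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        queue[tail] = w
                        tail += 1
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
        for k in range(cnt - 1, -1, -1):
            w = order[k]
            for v in range(n):
                if adj[v, w] and dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


@njit(cache=True)
def nodal_efficiency_k(adj):
    n = adj.shape[0]
    dist = distances_k(adj)
    eff = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j and dist[i, j] != np.inf:
                acc += 1.0 / dist[i, j]
        eff[i] = acc / (n - 1) if n > 1 else 0.0
    return eff


@njit(cache=True)
def local_efficiency_k(adj):
    """Global efficiency of each node's neighbour-induced subgraph (0 if k<2)."""
    n = adj.shape[0]
    out = np.zeros(n)
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.zeros((k, k), np.uint8)
        for a in range(k):
            for b in range(k):
                if a != b and adj[nbrs[a], nbrs[b]]:
                    sub[a, b] = 1
        dist = distances_k(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and dist[a, b] != np.inf:
                    acc += 1.0 / dist[a, b]
        out[i] = acc / (k * (k - 1))
    return out


@njit(cache=True)
def edges_of(adj):
    n = adj.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                m += 1
    edges = np.empty((m, 2), np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                edges[k, 0] = i
                edges[k, 1] = j
                k += 1
    return edges


@njit(cache=True)
def _rewire_inplace(adj, edges, n_attempts):
    """Maslov–Sneppen double-edge swaps; preserves the degree sequence exactly."""
    m = edges.shape[0]
    if m < 2:
        return 0
    done = 0
    # one uniform draw encodes (e1, e2, direction): x is uniform on
    # [0, 2m^2) and its integer part maps bijectively onto the triple
    mm2 = float(2 * m * m)
    for _ in range(n_attempts):
        xi = int(np.random.random() * mm2)
        e1 = xi % m
        e2 = (xi // m) % m
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if xi >= m * m:
            tmp = c
            c = d
            d = tmp
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        done += 1
    return done


@njit(cache=True)
def rewire_k(adj, n_swap_per_edge, seed):
    """Return a degree-preserving randomisation of ``adj`` (fresh array)."""
    np.random.seed(seed)
    out = adj.copy()
    edges = edges_of(out)
    _rewire_inplace(out, edges, n_swap_per_edge * edges.shape[0])
    return out


@njit(cache=True)
def null_cp_lp_k(adj, n_null, n_swap_per_edge, seed):
    """Mean Cp and Lp over ``n_null`` independently rewired copies of ``adj``."""
    np.random.seed(seed)
    base_edges = edges_of(adj)
    m = base_edges.shape[0]
    if m == 0:
        return np.nan, np.nan
    cp_acc = 0.0
    lp_acc = 0.0
    lp_n = 0
    for _ in range(n_null):
        a2 = adj.copy()
        ed = base_edges.copy()
        _rewire_inplace(a2, ed, n_swap_per_edge * m)
        cp, lp, _ = cp_lp_eglob_k(a2)
        cp_acc += cp
        if not np.isnan(lp):
            lp_acc += lp
            lp_n += 1
    cp_rand = cp_acc / n_null
    lp_rand = lp_acc / lp_n if lp_n > 0 else np.nan
    return cp_rand, lp_rand
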