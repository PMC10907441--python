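"""Independent brute-force oracles used to check the graph metrics.

Everything here works on a dense numpy adjacency matrix and avoids the
code paths (and the networkx algorithms) used by the implementation:
distances come from Floyd–Warshall, betweenness from explicit
shortest-path counting over those distances, clustering and density from
direct edge counting, modularity from the textbook double sum.
"""

from __future__ import annotations

import numpy as np

INF = np.inf


def adjacency(lag, order=None):
    nodes = order if order is not None else sorted(lag.graph.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=int)
    for u, v in lag.graph.edges:
        a[idx[u], idx[v]] = 1
    return nodes, a


def weighted_adjacency(lag, order=None):
    nodes = order if order is not None else sorted(lag.graph.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=float)
    for u, v, w in lag.graph.edges(data="weight"):
        a[idx[u], idx[v]] = w
    return nodes, a


def density_oracle(a: np.ndarray) -> float:
    n = a.shape[0]
    return a.sum() / (n * (n - 1))


def clustering_oracle(a: np.ndarray, v: int) -> float:
    nbrs = np.flatnonzero((a[v] | a[:, v]) > 0)
    nbrs = nbrs[nbrs != v]
    k = len(nbrs)
    if k < 2:
        return 0.0
    sub = a[np.ix_(nbrs, nbrs)]
    return sub.sum() / (k * (k - 1))


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def path_counts(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s->t paths, by dynamic programming
    over increasing distance."""
    n = a.shape[0]
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    maxd = int(d[np.isfinite(d)].max(initial=0))
    for length in range(1, maxd + 1):
        for s in range(n):
            for t in range(n):
                if d[s, t] == length:
                    # sum over first hops u with d[u, t] == length - 1
                    sigma[s, t] = sum(
                        sigma[u, t] for u in np.flatnonzero(a[s]) if d[u, t] == length - 1
                    )
    return sigma


def betweenness_oracle(a: np.ndarray) -> np.ndarray:
    """Unnormalized directed betweenness from explicit path counting."""
    n = a.shape[0]
    d = floyd_warshall(a)
    sigma = path_counts(a, d)
    b = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(d[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    b[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return b


def modularity_oracle(w: np.ndarray, labels, resolution: float = 1.0) -> float:
    """Newman modularity on a symmetric weighted adjacency, double sum."""
    sym = w + w.T  # undirected projection: reciprocal weights summed
    two_m = sym.sum()
    if two_m == 0:
        return 0.0
    k = sym.sum(axis=1)
    q = 0.0
    n = sym.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += sym[i, j] - resolution * k[i] * k[j] / two_m
    return q / two_m
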