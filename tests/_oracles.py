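"""Brute-force graph-metric oracles used by the test suites.

Deliberately naive (pure-python BFS, explicit triangle counts) and
independent of the implementation under test.
"""

from itertools import combinations

import numpy as np


def bfs_distances(adj):
    n = len(adj)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        seen = {s}
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u][v] and v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def brute_cc(adj):
    n = len(adj)
    total = 0.0
    for k in range(n):
        nb = [i for i in range(n) if adj[k][i]]
        if len(nb) < 2:
            continue
        links = sum(adj[i][j] for i, j in combinations(nb, 2))
        total += 2.0 * links / (len(nb) * (len(nb) - 1))
    return total / n


def brute_L(adj):
    d = bfs_distances(adj)
    off = ~np.eye(len(adj), dtype=bool)
    finite = np.isfinite(d) & off
    return d[finite].mean(), 1 - finite.sum() / off.sum()


def brute_eglobal(adj):
    d = bfs_distances(adj)
    off = ~np.eye(len(adj), dtype=bool)
    inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return inv[off].mean()


def brute_elocal(adj):
    adj = np.asarray(adj)
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size >= 2:
            total += brute_eglobal(adj[np.ix_(nb, nb)])
    return total / n


def random_symmetric_adjacency(rng, n_min=3, n_max=7, p_lo=0.3, p_hi=0.9):
    n = int(rng.integers(n_min, n_max + 1))
    p = rng.uniform(p_lo, p_hi)
    a = (rng.uniform(size=(n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a | a.T
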