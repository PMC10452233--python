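"""Binary graph topology: proportional threshold, five graph metrics, and a
degree-preserving, connectedness-preserving random-network null.

Metrics follow the standard binary-undirected definitions: mean local
clustering (nodes with degree < 2 contribute 0), characteristic path
length over reachable ordered pairs (the unreachable fraction is reported
alongside), global efficiency with 1/infinity = 0, local efficiency as
the mean global efficiency of each node's neighbour subgraph, and
small-worldness sigma = (CC/CC_rand) / (L/L_rand) against the mean of an
ensemble of Maslov-Sneppen randomized graphs with the same degree
sequence, constrained to stay connected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)


@dataclass
class GraphMetrics:
    CC: float
    L: float
    sigma: float
    Eglobal: float
    Elocal: float
    CC_rand: float
    L_rand: float
    n_random: int
    unreachable_fraction: float


def _check_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return a.astype(np.int8)


def threshold_proportional(w: np.ndarray, density: float = 0.10) -> np.ndarray:
    """Binarize a weight matrix by keeping the ceil(density * N(N-1)/2)
    largest upper-triangle weights.  Ties at the cutoff are broken by
    lexicographic (i, j) order so the result is deterministic.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vals = w[ii, jj]
    k = math.ceil(density * vals.size)
    if np.unique(vals).size == 1:
        logger.warning("all weights equal; keeping the first %d edges by index", k)
    order = np.lexsort((jj, ii, -vals))  # primary: weight desc, then (i, j)
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[keep], jj[keep]] = 1
    return adj | adj.T


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(a), method="D", unweighted=True)


def clustering_coefficient(a: np.ndarray) -> float:
    """Mean local triangle density; degree-<2 nodes contribute 0."""
    a = _check_adjacency(a).astype(float)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(deg >= 2, 2.0 * tri / (deg * (deg - 1.0)), 0.0)
    return float(local.mean())


def characteristic_path_length(a: np.ndarray) -> tuple[float, float]:
    """(mean shortest path over reachable ordered pairs, unreachable fraction)."""
    a = _check_adjacency(a)
    if a.sum() == 0:
        return np.nan, 1.0
    d = _distance_matrix(a)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    unreachable = 1.0 - finite.sum() / off.sum()
    return float(d[finite].mean()), float(unreachable)


def global_efficiency(a: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    a = _check_adjacency(a)
    n = a.shape[0]
    if n < 2 or a.sum() == 0:
        return 0.0
    d = _distance_matrix(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].mean())


def local_efficiency(a: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph."""
    a = _check_adjacency(a)
    eff = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        nb = np.flatnonzero(a[i])
        if nb.size >= 2:
            eff[i] = global_efficiency(a[np.ix_(nb, nb)])
    return float(eff.mean())


def is_connected(a: np.ndarray) -> bool:
    return connected_components(csr_array(a), directed=False,
                                return_labels=False) == 1


def _attempt_swaps(edges: np.ndarray, eset: set, n_swaps: int,
                   rng: np.random.Generator) -> None:
    """In-place Maslov-Sneppen double-edge swaps; invalid proposals rejected."""
    m = len(edges)
    idx = rng.integers(0, m, size=(n_swaps, 2))
    flips = rng.random(n_swaps) < 0.5
    for (e1, e2), flip in zip(idx, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        n1 = (min(a, d), max(a, d))
        n2 = (min(c, b), max(c, b))
        if n1 in eset or n2 in eset:
            continue
        eset.discard((min(a, b), max(a, b)))
        eset.discard((min(c, d), max(c, d)))
        eset.add(n1)
        eset.add(n2)
        edges[e1] = n1
        edges[e2] = n2


def randomize_degree_preserving(a: np.ndarray, n: int = 100, seed: int = 0,
                                swap_factor: int = 10,
                                max_restarts: int = 100) -> list[np.ndarray]:
    """Ensemble of degree-matched random graphs, each connected.

    Each member starts from the original edge set and undergoes
    swap_factor*|E| attempted double-edge swaps; a member that ends up
    disconnected is re-randomized (fresh swap sequence) up to max_restarts
    times.  Graphs too small to randomize are returned as copies with a
    warning.
    """
    a = _check_adjacency(a)
    ii, jj = np.nonzero(np.triu(a, k=1))
    base_edges = np.stack([ii, jj], axis=1)
    if len(base_edges) < 2:
        logger.warning("graph too small to randomize; returning copies")
        return [a.copy() for _ in range(n)]
    if not is_connected(a):
        raise ValueError("randomization null requires a connected graph")
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n):
        out = None
        for _attempt in range(max_restarts):
            edges = base_edges.copy()
            eset = {(int(u), int(v)) for u, v in edges}
            _attempt_swaps(edges, eset, swap_factor * len(edges), rng)
            cand = np.zeros_like(a)
            cand[edges[:, 0], edges[:, 1]] = 1
            cand |= cand.T
            if is_connected(cand):
                out = cand
                break
        if out is None:
            logger.warning("could not reach a connected randomization in "
                           "%d restarts; using the original graph", max_restarts)
            out = a.copy()
        members.append(out)
    return members


def small_worldness(a: np.ndarray, ensemble: list[np.ndarray]) -> GraphMetrics:
    """sigma = (CC/CC_rand) / (L/L_rand) with ensemble-mean references."""
    cc = clustering_coefficient(a)
    path_l, unreach = characteristic_path_length(a)
    cc_rand = float(np.mean([clustering_coefficient(g) for g in ensemble]))
    l_rand = float(np.mean([characteristic_path_length(g)[0] for g in ensemble]))
    if cc_rand <= 0 or l_rand <= 0 or not np.isfinite(path_l):
        sigma = np.nan
    else:
        sigma = (cc / cc_rand) / (path_l / l_rand)
    return GraphMetrics(CC=cc, L=path_l, sigma=float(sigma),
                        Eglobal=global_efficiency(a),
                        Elocal=local_efficiency(a),
                        CC_rand=cc_rand, L_rand=l_rand,
                        n_random=len(ensemble),
                        unreachable_fraction=unreach)


def graph_metrics(weights: np.ndarray, density: float = 0.10,
                  n_random: int = 100, seed: int = 0) -> GraphMetrics:
    """Threshold a weight matrix and compute all five metrics plus the null.

    When the thresholded graph is disconnected the random-network null is
    undefined under the connectedness constraint; sigma is then NaN and the
    remaining metrics are still reported.
    """
    adj = threshold_proportional(weights, density)
    if is_connected(adj):
        ens = randomize_degree_preserving(adj, n=n_random, seed=seed)
        return small_worldness(adj, ens)
    logger.warning("thresholded graph disconnected; sigma undefined")
    path_l, unreach = characteristic_path_length(adj)
    return GraphMetrics(CC=clustering_coefficient(adj), L=path_l,
                        sigma=np.nan, Eglobal=global_efficiency(adj),
                        Elocal=local_efficiency(adj), CC_rand=np.nan,
                        L_rand=np.nan, n_random=0,
                        unreachable_fraction=unreach)
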