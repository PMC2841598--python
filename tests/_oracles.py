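"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, double loops, bitmask
subset scans) and shares no code with the package implementations it checks.
"""

from __future__ import annotations

from collections import Counter, deque
from itertools import combinations

import networkx as nx
import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Least squares via the normal equations (pinv); returns (beta, rss)."""
    beta = np.linalg.pinv(X.T @ X) @ X.T @ y
    resid = y - X @ beta
    return beta, float(resid @ resid)


def bf_k_core(g: nx.Graph, k: int) -> set:
    """Vertex set of the maximal subgraph of min degree >= k, by subset scan.

    Uses the fact that the union of qualifying vertex subsets qualifies, so
    the k-core is the union of all subsets whose induced min degree is >= k.
    """
    nodes = list(g.nodes())
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in g.edges():
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    best = 0
    for mask in range(1, 1 << n):
        ok = True
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if (adj[i] & mask).bit_count() < k:
                ok = False
                break
            m &= m - 1
        if ok:
            best |= mask
    return {nodes[i] for i in range(n) if best >> i & 1}


def bf_highest_k_core(g: nx.Graph) -> tuple[set, int]:
    k = 0
    best = bf_k_core(g, 0)
    while True:
        nxt = bf_k_core(g, k + 1)
        if not nxt:
            return best, k
        best, k = nxt, k + 1


def bf_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return g.number_of_edges() / (n * (n - 1) / 2)


def bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def bf_closeness(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes():
        dist = bfs_distances(g, v)
        others = [d for u, d in dist.items() if u != v]
        out[v] = len(others) / sum(others) if others else 0.0
    return out


def bf_path_stats(g: nx.Graph) -> tuple[float, int, bool]:
    """(mean shortest path, diameter, defined) over connected pairs."""
    dists = []
    for u, v in combinations(g.nodes(), 2):
        d = bfs_distances(g, u).get(v)
        if d is not None:
            dists.append(d)
    if not dists:
        return 0.0, 0, False
    return sum(dists) / len(dists), max(dists), True


def bf_shared_neighbors(g: nx.Graph) -> dict[int, int]:
    counts: Counter[int] = Counter()
    for u, v in combinations(g.nodes(), 2):
        shared = sum(1 for w in g.nodes() if g.has_edge(u, w) and g.has_edge(v, w))
        if shared:
            counts[shared] += 1
    return dict(counts)


def bf_topological_coefficient(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes():
        k_v = g.degree(v)
        if k_v < 2:
            out[v] = 0.0
            continue
        ratios = []
        for j in g.nodes():
            if j == v:
                continue
            shared = sum(1 for w in g.nodes() if g.has_edge(v, w) and g.has_edge(j, w))
            if shared == 0:
                continue
            ratios.append((shared + (1 if g.has_edge(v, j) else 0)) / k_v)
        out[v] = sum(ratios) / len(ratios) if ratios else 0.0
    return out


def random_graphs(n_graphs: int, max_nodes: int, seed: int):
    """Seeded ensemble of small Erdos-Renyi graphs (possibly disconnected)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.9))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for u, v in combinations(range(n), 2):
            if rng.random() < p:
                g.add_edge(u, v)
        yield g
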