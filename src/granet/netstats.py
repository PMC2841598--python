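"""Structural statistics of an (association) graph.

Covers the summary used to contrast an inferred network with a random one:
size, sparsity, components, path lengths, degree distribution, shared
neighbor distribution, closeness centrality and topological coefficients.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = [
    "NetworkStats",
    "degree_distribution",
    "shared_neighbor_distribution",
    "closeness_centrality",
    "topological_coefficient",
    "summary",
]


def degree_distribution(g: nx.Graph) -> dict[int, float]:
    """Normalized histogram p(k) of vertex degrees."""
    n = g.number_of_nodes()
    if n == 0:
        return {}
    counts = Counter(d for _, d in g.degree())
    return {k: counts[k] / n for k in sorted(counts)}


def shared_neighbor_distribution(g: nx.Graph) -> dict[int, int]:
    """Counts of unordered vertex pairs by number of shared neighbors (>= 1)."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    counts: Counter[int] = Counter()
    for u, v in combinations(g.nodes(), 2):
        shared = len(adj[u] & adj[v])
        if shared >= 1:
            counts[shared] += 1
    return {k: counts[k] for k in sorted(counts)}


def closeness_centrality(g: nx.Graph) -> dict:
    """C(v) = 1 / mean shortest-path length to the nodes reachable from v.

    Isolated nodes (no reachable partner) score 0.
    """
    closeness = {}
    for v in g.nodes():
        lengths = nx.single_source_shortest_path_length(g, v)
        total = sum(lengths.values())
        reachable = len(lengths) - 1
        closeness[v] = reachable / total if total > 0 else 0.0
    return closeness


def topological_coefficient(g: nx.Graph) -> tuple[dict, dict[int, float]]:
    """Per-node TC and its average TC(k) over nodes of equal degree.

    For a node v of degree >= 2, TC(v) averages J(v, j) / deg(v) over every
    node j sharing at least one neighbor with v, where J counts the common
    neighbors plus 1 if v and j are directly linked.  Nodes of degree < 2 or
    without sharing partners score 0 and are excluded from the TC(k) means.
    """
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    tc: dict = {}
    by_degree: dict[int, list[float]] = {}
    for v in g.nodes():
        k_v = len(adj[v])
        if k_v < 2:
            tc[v] = 0.0
            continue
        ratios = []
        for j in g.nodes():
            if j == v:
                continue
            shared = len(adj[v] & adj[j])
            if shared == 0:
                continue
            ratios.append((shared + (1 if j in adj[v] else 0)) / k_v)
        if not ratios:
            tc[v] = 0.0
            continue
        tc[v] = sum(ratios) / len(ratios)
        by_degree.setdefault(k_v, []).append(tc[v])
    tc_by_degree = {k: sum(vals) / len(vals) for k, vals in sorted(by_degree.items())}
    return tc, tc_by_degree


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    sparsity: float  # fraction of possible *directed* edges present
    n_connected_components: int
    mean_shortest_path: float
    diameter: int
    path_stats_defined: bool
    degree_distribution: dict[int, float] = field(default_factory=dict)
    shared_neighbor_distribution: dict[int, int] = field(default_factory=dict)
    closeness: dict = field(default_factory=dict)
    topological_coefficient: dict = field(default_factory=dict)
    tc_by_degree: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "sparsity": self.sparsity,
            "n_connected_components": self.n_connected_components,
            "mean_shortest_path": self.mean_shortest_path,
            "diameter": self.diameter,
            "path_stats_defined": self.path_stats_defined,
            "degree_distribution": {str(k): v for k, v in self.degree_distribution.items()},
            "shared_neighbor_distribution": {
                str(k): v for k, v in self.shared_neighbor_distribution.items()
            },
            "closeness": {str(k): v for k, v in self.closeness.items()},
            "topological_coefficient": {
                str(k): v for k, v in self.topological_coefficient.items()
            },
            "tc_by_degree": {str(k): v for k, v in self.tc_by_degree.items()},
        }


def summary(g: nx.Graph) -> NetworkStats:
    """Assemble all statistics; path lengths are over connected pairs only.

    An edgeless graph has undefined path statistics, reported as 0 with
    ``path_stats_defined = False``.
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    sparsity = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0

    total, pairs, diameter = 0, 0, 0
    for v in g.nodes():
        for dist in nx.single_source_shortest_path_length(g, v).values():
            if dist > 0:
                total += dist
                pairs += 1
                diameter = max(diameter, dist)
    defined = pairs > 0
    mean_path = total / pairs if defined else 0.0

    tc, tc_k = topological_coefficient(g)
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        sparsity=sparsity,
        n_connected_components=nx.number_connected_components(g) if n else 0,
        mean_shortest_path=mean_path,
        diameter=diameter,
        path_stats_defined=defined,
        degree_distribution=degree_distribution(g),
        shared_neighbor_distribution=shared_neighbor_distribution(g),
        closeness=closeness_centrality(g),
        topological_coefficient=tc,
        tc_by_degree=tc_k,
    )
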