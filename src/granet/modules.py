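"""Dense-region ("complex") detection in an association graph.

Purely topological: vertices are weighted by the density of the highest
k-core of their closed neighborhood, complexes are grown greedily from the
highest-weight unseen vertex, and post-processing filters complexes without
a 2-core and trims singly-connected vertices.  A complex is scored by
density x vertex count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .exceptions import ValidationError

__all__ = [
    "VertexWeight",
    "Complex",
    "graph_density",
    "k_core",
    "highest_k_core",
    "vertex_weights",
    "score_complex",
    "find_complexes",
]


def graph_density(g: nx.Graph) -> float:
    """|E| over |V|(|V|-1)/2; graphs with fewer than 2 vertices score 0."""
    n = g.number_of_nodes()
    if n < 2:
        warnings.warn("density of a graph with < 2 vertices is defined as 0",
                      stacklevel=2)
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return 0.0 if n < 2 else 2.0 * g.number_of_edges() / (n * (n - 1))


def k_core(g: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph of minimum degree >= k, by iterative peeling; may be empty."""
    if k < 0:
        raise ValidationError("k must be non-negative")
    core = g.copy()
    while True:
        doomed = [v for v, d in core.degree() if d < k]
        if not doomed:
            return core
        core.remove_nodes_from(doomed)


def highest_k_core(g: nx.Graph) -> tuple[nx.Graph, int]:
    """The non-empty k-core with the largest k, and that k (k_max).

    An empty graph yields ``(empty graph, 0)``.
    """
    if g.number_of_nodes() == 0:
        return g.copy(), 0
    best, k_max = k_core(g, 0), 0
    k = 1
    while True:
        core = k_core(best, k)  # cores are nested, peel from the previous one
        if core.number_of_nodes() == 0:
            return best, k_max
        best, k_max = core, k
        k += 1


@dataclass(frozen=True)
class VertexWeight:
    vertex: object
    k_max: int
    core_density: float

    @property
    def weight(self) -> float:
        return self.k_max * self.core_density


def vertex_weights(g: nx.Graph) -> dict:
    """Weight each vertex by k_max x density of its closed neighborhood's highest core.

    The closed neighborhood is the vertex plus its direct neighbors with the
    induced edges.  Isolated vertices weigh 0.
    """
    weights = {}
    for v in g.nodes():
        closed = g.subgraph([v, *g.neighbors(v)])
        core, k_max = highest_k_core(closed)
        weights[v] = VertexWeight(v, k_max, _density(core))
    return weights


@dataclass
class Complex:
    """A detected dense subgraph."""

    vertices: tuple
    n_edges: int
    density: float
    score: float
    seed: object
    rank: int = 0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def score_complex(g: nx.Graph) -> float:
    """Density x vertex count of the (sub)graph; singletons score 0 with a warning."""
    if g.number_of_nodes() < 2:
        warnings.warn("complex with < 2 vertices scores 0", stacklevel=2)
        return 0.0
    return _density(g) * g.number_of_nodes()


def _sort_key(v) -> str:
    return str(v)


def find_complexes(
    g: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    min_core: int = 2,
) -> list[Complex]:
    """Greedy seeded expansion into vertex-disjoint dense complexes.

    Seeds are taken in order of decreasing vertex weight (ties by vertex id).
    From a seed of weight w, traversal recursively includes unseen neighbors
    whose weight exceeds ``(1 - vwp) * w``.  Post-processing drops complexes
    lacking a ``min_core``-core; with ``haircut`` singly-connected vertices
    are trimmed (iterated until stable).  Output is sorted by score
    descending, then size descending, then seed id.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValidationError("vwp must be in [0, 1)")
    if min_core < 0:
        raise ValidationError("min_core must be non-negative")

    weights = {v: vw.weight for v, vw in vertex_weights(g).items()}
    order = sorted(g.nodes(), key=lambda v: (-weights[v], _sort_key(v)))
    seen: set = set()
    complexes: list[Complex] = []

    for seed in order:
        if seed in seen:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        seen.add(seed)
        stack = [seed]
        while stack:
            u = stack.pop()
            for nb in sorted(g.neighbors(u), key=_sort_key):
                if nb not in seen and weights[nb] > threshold:
                    seen.add(nb)
                    members.add(nb)
                    stack.append(nb)

        sub = g.subgraph(members).copy()
        if k_core(sub, min_core).number_of_nodes() == 0:
            continue
        if haircut:
            sub = k_core(sub, 2)
        if sub.number_of_nodes() < 2:
            continue
        complexes.append(
            Complex(
                vertices=tuple(sorted(sub.nodes(), key=_sort_key)),
                n_edges=sub.number_of_edges(),
                density=_density(sub),
                score=score_complex(sub),
                seed=seed,
            )
        )

    complexes.sort(key=lambda c: (-c.score, -c.n_vertices, _sort_key(c.seed)))
    for rank, c in enumerate(complexes, start=1):
        c.rank = rank
    return complexes
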