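"""Association networks from directed causality strengths, plus baselines.

The undirected association weight of a gene pair is the larger of its two
directional causality statistics (zero when neither direction passes the
test).  Quantile thresholding keeps only the dominant edges.  Pearson
correlation and Euclidean distance matrices are provided as comparison
baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import ValidationError
from .preprocess import ExpressionMatrix

__all__ = [
    "DirectedStrengthMatrix",
    "ThresholdRecord",
    "AssociationNetwork",
    "symmetrize_max",
    "threshold_quantile",
    "correlation_matrix",
    "euclidean_matrix",
]


def _check_square(values: np.ndarray, n_ids: int, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{what} must be square, got shape {values.shape}")
    if values.shape[0] != n_ids:
        raise ValidationError(
            f"{what} size {values.shape[0]} does not match {n_ids} gene ids"
        )
    if values.size and values.min() < 0:
        raise ValidationError(f"{what} entries must be non-negative")
    return values


@dataclass
class DirectedStrengthMatrix:
    """Per-direction causality strengths; entry (i, j) is the strength of j -> i."""

    gene_ids: list[str]
    values: np.ndarray
    alpha: float
    p_max: int | None = None
    n_tests: int = 0

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, len(self.gene_ids), "strength matrix")
        np.fill_diagonal(self.values, 0.0)


class ThresholdRecord(NamedTuple):
    q: float
    cutoff: float


@dataclass
class AssociationNetwork:
    """Symmetric non-negative weight matrix over genes, optionally thresholded."""

    gene_ids: list[str]
    weights: np.ndarray
    threshold: ThresholdRecord | None = None

    def __post_init__(self) -> None:
        self.weights = _check_square(self.weights, len(self.gene_ids), "weight matrix")
        if not np.allclose(self.weights, self.weights.T):
            raise ValidationError("weight matrix must be symmetric")
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def edges(self) -> list[tuple[str, str, float]]:
        """Positive-weight edges as (gene_a, gene_b, weight), i < j order."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [
            (self.gene_ids[i], self.gene_ids[j], float(self.weights[i, j]))
            for i, j in zip(ii, jj)
        ]

    @property
    def n_edges(self) -> int:
        return int((np.triu(self.weights, k=1) > 0).sum())

    def to_graph(self, include_isolated: bool = True) -> nx.Graph:
        g = nx.Graph()
        if include_isolated:
            g.add_nodes_from(self.gene_ids)
        g.add_weighted_edges_from(self.edges())
        return g


def symmetrize_max(d: DirectedStrengthMatrix) -> AssociationNetwork:
    """Undirected association: w(i, j) = max of the two directional strengths."""
    return AssociationNetwork(
        gene_ids=list(d.gene_ids), weights=np.maximum(d.values, d.values.T)
    )


def threshold_quantile(a: AssociationNetwork, q: float) -> AssociationNetwork:
    """Keep edges at or above the empirical q-quantile of the positive weights.

    The quantile (linear interpolation between order statistics) is computed
    over the existing positive edge weights only; structural zeros do not
    dilute the cutoff.  Nodes are left in place, so isolated nodes may remain.
    """
    if not 0.0 < q < 1.0:
        raise ValidationError("q must be in (0, 1)")
    upper = np.triu(a.weights, k=1)
    positive = upper[upper > 0]
    if positive.size == 0:
        raise ValidationError("no edges to threshold")
    cutoff = float(np.quantile(positive, q))
    kept = np.where(a.weights >= cutoff, a.weights, 0.0)
    return AssociationNetwork(
        gene_ids=list(a.gene_ids),
        weights=kept,
        threshold=ThresholdRecord(q=q, cutoff=cutoff),
    )


def correlation_matrix(m: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation over time points; diagonal 1.

    Zero-variance rows make the corresponding entries undefined; they are
    reported as NaN with a warning.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else np.atleast_2d(np.asarray(m, float))
    flat = values.std(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s); their correlations are NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, np.where(~flat, 1.0, np.nan))
    return corr


def euclidean_matrix(m: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance over time points; diagonal 0."""
    values = m.values if isinstance(m, ExpressionMatrix) else np.atleast_2d(np.asarray(m, float))
    if values.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(values, metric="euclidean"))
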