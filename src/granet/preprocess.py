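"""Expression-matrix container and preparation steps for causality testing.

Stationarity is approximated by first differencing; flat (low-fluctuation)
profiles are removed with a range-versus-reference-sigma rule; large gene
sets can be reduced to the spectrally most active genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ExpressionMatrix",
    "first_difference",
    "filter_flat",
    "spectral_power",
    "rank_by_spectral_power",
]


@dataclass
class ExpressionMatrix:
    """Genes x ordered time points.

    ``gene_ids`` are unique strings, ``values`` a ``(n_genes, T)`` float
    matrix with finite entries, and ``time_labels`` the ordered column names.
    """

    gene_ids: list[str]
    values: np.ndarray
    time_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.time_labels:
            self.time_labels = [f"t{t}" for t in range(1, self.values.shape[1] + 1)]
        self.time_labels = [str(t) for t in self.time_labels]
        if self.values.shape != (len(self.gene_ids), len(self.time_labels)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.time_labels)} time labels"
            )
        seen: set[str] = set()
        dupes = sorted({g for g in self.gene_ids if g in seen or seen.add(g)})
        if dupes:
            raise ValidationError(f"duplicate gene ids: {', '.join(dupes)}")
        if self.values.size and not np.isfinite(self.values).all():
            g, t = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value for gene '{self.gene_ids[g]}' "
                f"at time '{self.time_labels[t]}'"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, indices) -> "ExpressionMatrix":
        indices = list(indices)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in indices],
            self.values[indices].copy() if indices else np.empty((0, self.n_times)),
            list(self.time_labels),
        )


def first_difference(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every profile by its successive differences (T-1 columns)."""
    if m.n_times < 2:
        raise ValidationError("first differencing needs at least 2 time points")
    return ExpressionMatrix(
        list(m.gene_ids), np.diff(m.values, axis=1), list(m.time_labels[1:])
    )


def filter_flat(
    m: ExpressionMatrix, k: float = 2.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose temporal range falls below ``k`` reference sigmas.

    The reference sigma is the median of the per-gene temporal standard
    deviations, making the rule scale-free across datasets.  A gene is
    removed iff ``max - min < k * sigma_ref``.  If the reference sigma is 0
    (degenerate all-flat input) nothing is removed and a warning is issued.
    """
    if m.n_times < 2:
        raise ValidationError("flat filtering needs at least 2 time points")
    if k < 0:
        raise ValidationError("k must be non-negative")
    sds = m.values.std(axis=1, ddof=1)
    sigma_ref = float(np.median(sds)) if sds.size else 0.0
    if sigma_ref == 0.0:
        warnings.warn(
            "reference sigma is 0 (all profiles flat); no gene removed",
            stacklevel=2,
        )
        return m.subset(range(m.n_genes)), []
    ranges = m.values.max(axis=1) - m.values.min(axis=1)
    keep = ranges >= k * sigma_ref
    removed = [g for g, ok in zip(m.gene_ids, keep) if not ok]
    if not keep.any():
        warnings.warn("every gene was flagged as flat; returning an empty matrix",
                      stacklevel=2)
    return m.subset(np.flatnonzero(keep)), removed


def spectral_power(values: np.ndarray) -> np.ndarray:
    """Per-row sum of squared DFT magnitudes over nonzero frequencies.

    The DC bin is excluded so that a constant offset contributes nothing;
    both half-spectra of the real-input DFT are summed.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    spectra = np.fft.fft(values, axis=1)
    return (np.abs(spectra[:, 1:]) ** 2).sum(axis=1)


def rank_by_spectral_power(m: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Keep the ``top_n`` genes with the highest spectral power, in descending order.

    Ties are broken by input order (stable sort).
    """
    if top_n <= 0:
        raise ValidationError("top_n must be positive")
    if top_n > m.n_genes:
        raise ValidationError(
            f"top_n ({top_n}) exceeds the number of genes ({m.n_genes})"
        )
    scores = spectral_power(m.values)
    order = np.argsort(-scores, kind="stable")[:top_n]
    return m.subset(order)
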