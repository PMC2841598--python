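"""Simulation of multivariate autoregressive systems with known causal lag structure.

The three benchmark systems (``dataset1``-``dataset3``) and their 15-process
union (``combined_system``) are linear stochastic processes in which a small
set of cross-process lag terms defines the ground-truth interaction network.
Arbitrary systems can be simulated from a :class:`VARSpec`.

Seeding uses one independent noise substream per process (spawned from the
master seed), so embedding a system inside a larger one leaves the shared
processes bitwise identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DivergenceError, ValidationError

__all__ = [
    "VARSpec",
    "SimulatedSeries",
    "simulate_var",
    "true_edges",
    "dataset1_spec",
    "dataset2_spec",
    "dataset3_spec",
    "combined_spec",
    "dataset1",
    "dataset2",
    "dataset3",
    "combined_system",
    "COMBINED_BLOCKS",
]

#: Runtime stability guard: any simulated value beyond this aborts the run.
DIVERGENCE_LIMIT = 1e12

#: Process index blocks of the combined 15-process system (1-based, inclusive).
COMBINED_BLOCKS = ((1, 2, 3, 4, 5), (6, 7, 8, 9), (10, 11, 12, 13, 14, 15))


@dataclass(frozen=True)
class VARSpec:
    """Coefficient/lag structure of a linear autoregressive system.

    Parameters
    ----------
    n_processes
        Number of processes in the system.
    terms
        Iterable of ``(target, source, lag, coefficient)`` tuples with
        1-based process indices and ``lag >= 1``.  A term contributes
        ``coefficient * x_source[t - lag]`` to ``x_target[t]``.
    noise_sd
        Per-process innovation standard deviation; a scalar is broadcast.
    initial_values
        Values used for times before the first simulated step; a scalar is
        broadcast.
    """

    n_processes: int
    terms: tuple[tuple[int, int, int, float], ...] = ()
    noise_sd: tuple[float, ...] = 1.0  # type: ignore[assignment]
    initial_values: tuple[float, ...] = 0.0  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_processes < 1:
            raise ValidationError("n_processes must be a positive integer")
        norm_terms = []
        for term in self.terms:
            tgt, src, lag, coef = term
            for idx, name in ((tgt, "target"), (src, "source")):
                if not 1 <= int(idx) <= self.n_processes:
                    raise ValidationError(
                        f"{name} index {idx} outside [1, {self.n_processes}]"
                    )
            if int(lag) < 1:
                raise ValidationError(f"lag must be >= 1, got {lag}")
            if not math.isfinite(float(coef)):
                raise ValidationError(f"non-finite coefficient in term {term}")
            norm_terms.append((int(tgt), int(src), int(lag), float(coef)))
        object.__setattr__(self, "terms", tuple(norm_terms))
        object.__setattr__(self, "noise_sd", self._broadcast(self.noise_sd, "noise_sd"))
        object.__setattr__(
            self, "initial_values", self._broadcast(self.initial_values, "initial_values")
        )
        if any(sd < 0 for sd in self.noise_sd):
            raise ValidationError("noise_sd must be non-negative")

    def _broadcast(self, value, name: str) -> tuple[float, ...]:
        if np.isscalar(value):
            return (float(value),) * self.n_processes
        values = tuple(float(v) for v in value)
        if len(values) != self.n_processes:
            raise ValidationError(
                f"{name} must have one entry per process "
                f"({len(values)} given, {self.n_processes} expected)"
            )
        return values

    @property
    def max_lag(self) -> int:
        return max((lag for _, _, lag, _ in self.terms), default=0)


def true_edges(spec: VARSpec) -> frozenset[tuple[int, int]]:
    """Unordered process pairs linked by at least one cross-process term."""
    pairs = set()
    for tgt, src, _, _ in spec.terms:
        if tgt != src:
            pairs.add((min(tgt, src), max(tgt, src)))
    return frozenset(pairs)


@dataclass(frozen=True)
class SimulatedSeries:
    """Output of :func:`simulate_var`: an ``n_processes x T`` matrix plus provenance."""

    data: np.ndarray
    spec: VARSpec
    seed: int
    burn_in: int

    @property
    def n_processes(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def to_expression_matrix(self, prefix: str = "x"):
        """View the simulated system as an expression matrix (rows ``x1..xN``)."""
        from .preprocess import ExpressionMatrix

        ids = [f"{prefix}{i}" for i in range(1, self.n_processes + 1)]
        labels = [f"t{t}" for t in range(1, self.n_times + 1)]
        return ExpressionMatrix(ids, self.data.copy(), labels)


def simulate_var(spec: VARSpec, T: int, seed: int, burn_in: int = 100) -> SimulatedSeries:
    """Simulate ``spec`` for ``T`` retained time points after ``burn_in`` discarded ones.

    Each process value is the sum of its lag terms plus Gaussian noise drawn
    from an independent per-process substream of ``seed``.  Lagged references
    preceding the start of the simulation resolve to ``spec.initial_values``.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    if burn_in < 0:
        raise ValidationError("burn_in must be non-negative")
    if spec.max_lag > burn_in:
        raise ConfigurationError(
            f"burn_in ({burn_in}) must be at least the maximum lag ({spec.max_lag})"
        )

    n = spec.n_processes
    total = burn_in + T
    streams = np.random.SeedSequence(seed).spawn(n)
    noise = np.empty((n, total))
    for i in range(n):
        noise[i] = np.random.default_rng(streams[i]).normal(0.0, spec.noise_sd[i], total)

    init = np.asarray(spec.initial_values)
    x = np.empty((n, total))
    for t in range(total):
        col = noise[:, t].copy()
        for tgt, src, lag, coef in spec.terms:
            past = t - lag
            prev = x[src - 1, past] if past >= 0 else init[src - 1]
            col[tgt - 1] += coef * prev
        if np.max(np.abs(col)) > DIVERGENCE_LIMIT:
            raise DivergenceError(
                f"simulated value exceeded {DIVERGENCE_LIMIT:g} at step {t}; "
                "the specified system appears unstable"
            )
        x[:, t] = col

    return SimulatedSeries(data=x[:, burn_in:].copy(), spec=spec, seed=seed, burn_in=burn_in)


def _self_terms(indices, coef: float) -> list[tuple[int, int, int, float]]:
    return [(i, i, 1, coef) for i in indices]


def dataset1_spec(
    drive: float = 0.8,
    weak_drive: float = 0.2,
    self_coef: float = 0.4,
    feedback: float = 0.3,
    noise_sd: float = 1.0,
) -> VARSpec:
    """Five processes: 1 drives 2, 3 (weakly) and 4; 4 and 5 share a feedback loop.

    Cross terms: 1->2 (lag 2), 1->3 (lag 3), 1->4 (lag 2), 4<->5 (lag 1).
    """
    terms = _self_terms(range(1, 6), self_coef) + [
        (2, 1, 2, weak_drive),
        (3, 1, 3, weak_drive),
        (4, 1, 2, drive),
        (5, 4, 1, feedback),
        (4, 5, 1, feedback),
    ]
    return VARSpec(5, tuple(terms), noise_sd=noise_sd)


def dataset2_spec(
    drive: float = 0.8, self_coef: float = 0.4, noise_sd: float = 1.0
) -> VARSpec:
    """Four processes: 1->2 (lag 3), 2->3, and 1 and 3 jointly drive 4."""
    terms = _self_terms(range(1, 5), self_coef) + [
        (2, 1, 3, drive),
        (3, 2, 1, drive),
        (4, 1, 1, drive),
        (4, 3, 1, drive),
    ]
    return VARSpec(4, tuple(terms), noise_sd=noise_sd)


def dataset3_spec(
    drive: float = 0.8, self_coef: float = 0.4, noise_sd: float = 1.0
) -> VARSpec:
    """Six processes: a 1->2->3->4 chain, 5 driven by 2 and 4, 6 driven by 1, 5 and 3.

    Cross terms: 1->2 (lag 1), 2->3 (lag 2), 3->4 (lag 1), 2->5 (lag 2),
    4->5 (lag 1), 1->6 (lag 2), 5->6 (lag 1), 3->6 (lag 3).
    """
    terms = _self_terms(range(1, 7), self_coef) + [
        (2, 1, 1, drive),
        (3, 2, 2, drive),
        (4, 3, 1, drive),
        (5, 2, 2, drive),
        (5, 4, 1, drive),
        (6, 1, 2, drive),
        (6, 5, 1, drive),
        (6, 3, 3, drive),
    ]
    return VARSpec(6, tuple(terms), noise_sd=noise_sd)


def combined_spec(**kwargs) -> VARSpec:
    """The 15-process union: processes 1-5, 6-9 and 10-15 copy the three systems.

    The blocks share no cross terms, so the combined system contains three
    mutually independent subsystems.
    """
    parts = [dataset1_spec(**kwargs), dataset2_spec(**kwargs), dataset3_spec(**kwargs)]
    terms: list[tuple[int, int, int, float]] = []
    noise: list[float] = []
    init: list[float] = []
    offset = 0
    for part in parts:
        terms.extend(
            (tgt + offset, src + offset, lag, coef) for tgt, src, lag, coef in part.terms
        )
        noise.extend(part.noise_sd)
        init.extend(part.initial_values)
        offset += part.n_processes
    return VARSpec(offset, tuple(terms), noise_sd=tuple(noise), initial_values=tuple(init))


def dataset1(T: int = 1000, seed: int = 0, burn_in: int = 100, **kwargs) -> SimulatedSeries:
    return simulate_var(dataset1_spec(**kwargs), T, seed, burn_in)


def dataset2(T: int = 1000, seed: int = 0, burn_in: int = 100, **kwargs) -> SimulatedSeries:
    return simulate_var(dataset2_spec(**kwargs), T, seed, burn_in)


def dataset3(T: int = 1000, seed: int = 0, burn_in: int = 100, **kwargs) -> SimulatedSeries:
    return simulate_var(dataset3_spec(**kwargs), T, seed, burn_in)


def combined_system(
    T: int = 1000, seed: int = 0, burn_in: int = 100, **kwargs
) -> SimulatedSeries:
    """Simulate the 15-process union; rows 1-5 reproduce ``dataset1(T, seed)`` exactly."""
    return simulate_var(combined_spec(**kwargs), T, seed, burn_in)
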