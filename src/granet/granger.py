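"""Bivariate Granger causality testing.

For a directed question "does y help predict x?" two nested autoregressions
of x are fit by ordinary least squares: the restricted model uses x's own
lags only, the unrestricted model adds y's lags.  The exclusion hypothesis
(all cross-lag weights zero) is tested with an F statistic

    S = ((RSS_0 - RSS_1) / p) / (RSS_1 / (n_obs - 2p - 1))

where RSS_0 and RSS_1 are the restricted and unrestricted residual sums of
squares, p the lag order and n_obs the number of usable rows (T - p; no
presample padding).  The lag order is chosen per pair by minimising an AIC
over a bivariate vector autoregression scored on a common estimation window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import DegeneratePairError, ValidationError
from .preprocess import ExpressionMatrix

__all__ = [
    "ARFit",
    "FTest",
    "AICRecord",
    "GrangerResult",
    "default_p_max",
    "fit_restricted",
    "fit_unrestricted",
    "granger_statistic",
    "select_lag_aic",
    "granger_test",
    "pairwise_causality",
]

logger = logging.getLogger(__name__)

#: Relative RSS deficit below which RSS_0 < RSS_1 is treated as round-off.
RSS_TOL = 1e-10


@dataclass
class ARFit:
    """One OLS autoregression fit (restricted or unrestricted)."""

    kind: str  # "restricted" | "unrestricted"
    p: int
    intercept: float
    own_coefs: np.ndarray
    cross_coefs: np.ndarray | None
    residuals: np.ndarray
    rss: float
    n_obs: int
    degenerate: bool = False

    @property
    def n_params(self) -> int:
        return 1 + self.p * (1 if self.cross_coefs is None else 2)


class FTest(NamedTuple):
    statistic: float
    df1: int
    df2: int
    p_value: float
    perfect_fit: bool = False


@dataclass
class AICRecord:
    """Result of the per-pair lag-order scan."""

    p: int
    aic: float
    sigma: np.ndarray  # 2x2 residual covariance at the chosen lag
    m: int  # process dimension (2 for the bivariate scan)
    n: int  # common estimation-window length
    scanned: dict[int, float]  # lag -> AIC for every scored candidate


@dataclass
class GrangerResult:
    """Outcome of one directed test (does y Granger-cause x?)."""

    statistic: float
    lag: int
    df1: int
    df2: int
    p_value: float
    alpha: float
    reject: bool
    degenerate: bool = False
    reason: str | None = None


def default_p_max(T: int) -> int:
    """Largest scanned lag: min(4, floor((T - 2) / 4)), at least 1.

    Keeps short series (e.g. 21 differenced time points) testable while
    allowing lags up to 4 on long ones.
    """
    return max(1, min(4, (T - 2) // 4))


def _lag_columns(series: np.ndarray, p: int, start: int) -> list[np.ndarray]:
    """Columns ``series[t - i]`` for i = 1..p, rows t = start..T-1."""
    T = series.size
    return [series[start - i : T - i] for i in range(1, p + 1)]


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid) if resid.ndim == 1 else float((resid * resid).sum())
    return beta, resid, rss, rank < X.shape[1]


def _check_series(x: np.ndarray, p: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValidationError("series contains non-finite values")
    if p < 1:
        raise ValidationError("lag order must be >= 1")
    if x.size < 2 * p + 2:
        raise ValidationError(
            f"series of length {x.size} too short for lag {p} (needs >= {2 * p + 2})"
        )
    return x


def fit_restricted(x: np.ndarray, p: int) -> ARFit:
    """OLS fit of x_t on an intercept and x_{t-1}..x_{t-p} over the T-p usable rows.

    A rank-deficient design (e.g. a constant series) is returned with the
    ``degenerate`` flag set rather than raising.
    """
    x = _check_series(x, p)
    T = x.size
    X = np.column_stack([np.ones(T - p)] + _lag_columns(x, p, p))
    beta, resid, rss, degenerate = _ols(X, x[p:])
    return ARFit(
        kind="restricted",
        p=p,
        intercept=float(beta[0]),
        own_coefs=beta[1 : p + 1].copy(),
        cross_coefs=None,
        residuals=resid,
        rss=rss,
        n_obs=T - p,
        degenerate=degenerate,
    )


def fit_unrestricted(x: np.ndarray, y: np.ndarray, p: int) -> ARFit:
    """OLS fit of x_t on an intercept, x's lags and y's lags (2p + 1 parameters)."""
    x = _check_series(x, p)
    y = _check_series(y, p)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    T = x.size
    X = np.column_stack(
        [np.ones(T - p)] + _lag_columns(x, p, p) + _lag_columns(y, p, p)
    )
    beta, resid, rss, degenerate = _ols(X, x[p:])
    return ARFit(
        kind="unrestricted",
        p=p,
        intercept=float(beta[0]),
        own_coefs=beta[1 : p + 1].copy(),
        cross_coefs=beta[p + 1 :].copy(),
        residuals=resid,
        rss=rss,
        n_obs=T - p,
        degenerate=degenerate,
    )


def granger_statistic(rss0: float, rss1: float, p: int, n_obs: int) -> FTest:
    """F statistic and upper-tail p-value for the nested-model comparison.

    ``rss1 = 0`` (perfect unrestricted fit) yields ``S = inf`` with p-value 0
    and the ``perfect_fit`` flag; an RSS deficit within round-off clamps S
    to 0.
    """
    df1, df2 = p, n_obs - 2 * p - 1
    if df2 < 1:
        raise ValidationError(f"n_obs ({n_obs}) must exceed 2p + 1 ({2 * p + 1})")
    if rss0 < 0 or rss1 < 0:
        raise ValidationError("residual sums of squares must be non-negative")
    if rss1 == 0.0:
        warnings.warn("perfect unrestricted fit (RSS_1 = 0); S reported as inf",
                      stacklevel=2)
        return FTest(float("inf"), df1, df2, 0.0, True)
    diff = rss0 - rss1
    if diff < 0:
        if -diff > RSS_TOL * max(rss1, 1.0):
            warnings.warn(
                f"RSS_0 < RSS_1 beyond tolerance (deficit {-diff:.3e}); clamping S to 0",
                stacklevel=2,
            )
        diff = 0.0
    S = (diff / p) / (rss1 / df2)
    return FTest(float(S), df1, df2, float(stats.f.sf(S, df1, df2)), False)


def select_lag_aic(x: np.ndarray, y: np.ndarray, p_max: int) -> AICRecord:
    """Choose the lag order minimising an AIC over a bivariate VAR of (x, y).

    For each candidate p in 1..p_max the order-p vector autoregression of
    (x, y) is fit on a common window (rows p_max..T-1 so the scores are
    comparable), the 2x2 residual covariance sigma is estimated with a
    degrees-of-freedom correction (divisor n - (2p + 1), which keeps the
    post-selection F test close to its nominal level in small samples), and

        aic(p) = ln det(sigma) + 2 * m^2 * p / n

    with m = 2 and n the window length.  The smallest minimising p wins;
    candidates with a singular covariance are skipped with a warning.
    """
    x = _check_series(x, p_max)
    y = _check_series(y, p_max)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    T = x.size
    start = p_max
    n = T - start
    targets = np.column_stack([x[start:], y[start:]])

    best: AICRecord | None = None
    scanned: dict[int, float] = {}
    for p in range(1, p_max + 1):
        X = np.column_stack(
            [np.ones(n)] + _lag_columns(x, p, start) + _lag_columns(y, p, start)
        )
        _, resid, _, _ = _ols(X, targets)
        df = n - (2 * p + 1)
        if df < 1:
            warnings.warn(f"no residual degrees of freedom at lag {p}; candidate skipped",
                          stacklevel=2)
            continue
        sigma = (resid.T @ resid) / df
        det = float(np.linalg.det(sigma))
        if not np.isfinite(det) or det <= 0.0:
            warnings.warn(f"singular residual covariance at lag {p}; candidate skipped",
                          stacklevel=2)
            continue
        aic = float(np.log(det) + 2.0 * 4.0 * p / n)
        scanned[p] = aic
        if best is None or aic < best.aic:
            best = AICRecord(p=p, aic=aic, sigma=sigma, m=2, n=n, scanned=scanned)
    if best is None:
        raise DegeneratePairError("no lag order could be scored for this pair")
    best.scanned = scanned
    return best


def _no_edge(lag: int, n_obs: int, alpha: float, reason: str) -> GrangerResult:
    df2 = max(n_obs - 2 * lag - 1, 0)
    return GrangerResult(
        statistic=0.0,
        lag=lag,
        df1=lag,
        df2=df2,
        p_value=1.0,
        alpha=alpha,
        reject=False,
        degenerate=True,
        reason=reason,
    )


def granger_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    p: int | str = "auto",
    p_max: int | None = None,
) -> GrangerResult:
    """Test the direction y -> x (do y's lags improve the prediction of x?).

    With ``p="auto"`` the lag order is selected by :func:`select_lag_aic`.
    Degenerate fits yield a no-edge result with a recorded reason instead of
    raising, so all-pairs scans are robust.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    T = x.size
    if p_max is None:
        p_max = default_p_max(T)
    if p == "auto":
        try:
            lag = select_lag_aic(x, y, p_max).p
        except DegeneratePairError as exc:
            return _no_edge(1, T - 1, alpha, str(exc))
    else:
        lag = int(p)

    restricted = fit_restricted(x, lag)
    unrestricted = fit_unrestricted(x, y, lag)
    if restricted.degenerate or unrestricted.degenerate:
        which = "restricted" if restricted.degenerate else "unrestricted"
        return _no_edge(lag, unrestricted.n_obs, alpha, f"rank-deficient {which} design")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ftest = granger_statistic(restricted.rss, unrestricted.rss, lag, unrestricted.n_obs)
    return GrangerResult(
        statistic=ftest.statistic,
        lag=lag,
        df1=ftest.df1,
        df2=ftest.df2,
        p_value=ftest.p_value,
        alpha=alpha,
        reject=ftest.p_value < alpha,
    )


def pairwise_causality(
    m: "ExpressionMatrix | np.ndarray",
    alpha: float = 0.05,
    p_max: int | None = None,
    lag: int | str = "auto",
):
    """Run the directed test for every ordered gene pair (n(n-1) tests).

    Entry (i, j) of the returned matrix holds the F statistic of the
    direction j -> i when the test rejects at ``alpha``, and 0 otherwise.
    Degenerate pairs are recorded as 0 with a logged reason.
    """
    from .assoc import DirectedStrengthMatrix

    if isinstance(m, ExpressionMatrix):
        values, gene_ids = m.values, list(m.gene_ids)
    else:
        values = np.atleast_2d(np.asarray(m, dtype=float))
        gene_ids = [f"x{i}" for i in range(1, values.shape[0] + 1)]
    n = values.shape[0]
    if n < 2:
        raise ValidationError("pairwise causality needs at least 2 genes")

    strengths = np.zeros((n, n))
    n_tests = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            n_tests += 1
            try:
                result = granger_test(values[i], values[j], alpha=alpha, p=lag, p_max=p_max)
            except Exception as exc:  # keep the scan alive on pathological pairs
                logger.warning("pair %s -> %s failed: %s", gene_ids[j], gene_ids[i], exc)
                continue
            if result.degenerate:
                logger.info(
                    "pair %s -> %s degenerate: %s", gene_ids[j], gene_ids[i], result.reason
                )
            elif result.reject:
                strengths[i, j] = result.statistic
    return DirectedStrengthMatrix(
        gene_ids=gene_ids, values=strengths, alpha=alpha, p_max=p_max, n_tests=n_tests
    )
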