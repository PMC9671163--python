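"""Lag-resolved cross-correlation between recording and performance envelopes.

Three quantities per trial: *similarity* (the maximum Pearson correlation
over lags within ±L points), the *optimal lag* at which that maximum
occurs (positive lag = the recording precedes the performance), and
*synchrony* (the zero-lag correlation, a phase-alignment measure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CcEstimate",
    "lagged_correlation",
    "max_similarity",
    "zero_lag_synchrony",
    "classify_optimal_lags",
]

DEFAULT_MAX_LAG = 10  # points; 10 x 0.125 s = 1.25 s


@dataclass(frozen=True)
class CcEstimate:
    """Cross-correlation summary for one trial.

    ``coefficients[ell + max_lag]`` is the Pearson correlation at lag
    ``ell`` in [-max_lag, +max_lag]; undefined lags (zero-variance
    overlap) are NaN.
    """

    coefficients: np.ndarray
    max_lag: int
    max_coefficient: float
    optimal_lag: int
    zero_lag_coefficient: float
    interval: float = 0.125

    @property
    def optimal_lag_s(self) -> float:
        return self.optimal_lag * self.interval

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.max_lag, self.max_lag + 1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN when either side has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return math.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def lagged_correlation(recording, performance, max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """Pearson correlation at each lag ell in [-max_lag, +max_lag].

    At lag ell the correlation pairs recording[t] with performance[t+ell],
    so a positive ell means the recording precedes the performance.  Each
    lag's correlation is computed on the overlap region with that region's
    own means and SDs (no zero-padding).
    """
    rec = np.asarray(getattr(recording, "values", recording), dtype=float)
    perf = np.asarray(getattr(performance, "values", performance), dtype=float)
    if rec.shape != perf.shape or rec.ndim != 1:
        raise ValueError("recording and performance must be aligned 1-D sequences")
    L = int(max_lag)
    if rec.size <= 2 * L + 10:
        raise ValueError(f"series length {rec.size} too short for max_lag {L}")
    coeffs = np.empty(2 * L + 1)
    for i, ell in enumerate(range(-L, L + 1)):
        if ell >= 0:
            a, b = rec[: rec.size - ell], perf[ell:]
        else:
            a, b = rec[-ell:], perf[: perf.size + ell]
        coeffs[i] = _pearson(a, b)
    return coeffs


def max_similarity(coefficients: Sequence[float]) -> tuple[float, int]:
    """Maximum signed coefficient and its lag.

    Ties are broken toward the smallest |lag|, then toward the positive
    lag.  Lags are indexed symmetrically: a length-(2L+1) array spans
    [-L, +L].
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.size == 0 or coeffs.size % 2 == 0:
        raise ValueError("coefficient array must have odd length 2L+1")
    if np.all(np.isnan(coeffs)):
        raise ValueError("all lag coefficients are undefined")
    L = coeffs.size // 2
    lags = np.arange(-L, L + 1)
    best = np.nanmax(coeffs)
    candidates = lags[np.isclose(coeffs, best, rtol=0.0, atol=1e-12)]
    # prefer small |lag|; among equal |lag|, prefer the positive one
    optimal = min(candidates, key=lambda ell: (abs(ell), -ell))
    return float(best), int(optimal)


def zero_lag_synchrony(recording, performance) -> float:
    """Pearson correlation with no time shift (phase alignment)."""
    rec = np.asarray(getattr(recording, "values", recording), dtype=float)
    perf = np.asarray(getattr(performance, "values", performance), dtype=float)
    if rec.shape != perf.shape or rec.ndim != 1:
        raise ValueError("recording and performance must be aligned 1-D sequences")
    r = _pearson(rec, perf)
    if math.isnan(r):
        raise ValueError("zero-lag correlation undefined: a series has zero variance")
    return r


def cc_estimate(
    recording,
    performance,
    max_lag: int = DEFAULT_MAX_LAG,
    interval: float = 0.125,
    absolute: bool = False,
) -> CcEstimate:
    """Full per-trial cross-correlation summary.

    With ``absolute=True`` the similarity maximum is taken over |r(ell)|
    (the sign of the winning coefficient is retained).
    """
    coeffs = lagged_correlation(recording, performance, max_lag=max_lag)
    if absolute:
        _, opt = max_similarity(np.abs(coeffs))
        best = float(coeffs[opt + max_lag])
    else:
        best, opt = max_similarity(coeffs)
    zero = float(coeffs[max_lag])
    return CcEstimate(
        coefficients=coeffs,
        max_lag=int(max_lag),
        max_coefficient=best,
        optimal_lag=opt,
        zero_lag_coefficient=zero,
        interval=interval,
    )


def classify_optimal_lags(estimates: Sequence[CcEstimate] | Sequence[int]) -> float:
    """Fraction of trials whose optimal lag is nonnegative (recording
    precedes, or is aligned with, the performance)."""
    lags = [
        int(getattr(e, "optimal_lag", e))  # accept raw lags or CcEstimates
        for e in estimates
    ]
    if not lags:
        raise ValueError("need at least one estimate")
    return sum(1 for ell in lags if ell >= 0) / len(lags)
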