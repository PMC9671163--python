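"""Pairwise time-domain Granger causality via vector autoregression.

A series X "Granger-causes" Y when X's past improves prediction of Y
beyond Y's own past.  The magnitude is the log-ratio of residual
variances of two nested least-squares autoregressions of Y,

    F_{X->Y} = ln( sigma^2_reduced / sigma^2_full ),

where the reduced model regresses Y_t on its own p lags and the full
model adds the p lags of X (the Y-equation of the bivariate VAR(p)).
Both models are fitted by OLS on the same demeaned sample with the
maximum-likelihood variance divisor, so F >= 0 holds exactly.  F is
expressed in nats.

Model order p is chosen per trial by the Akaike information criterion
and, following the study design this package implements, the maximum
order across a participant's trials is then reused for all of that
participant's trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VarModel",
    "GcEstimate",
    "fit_var_ols",
    "aic_order_search",
    "select_participant_order",
    "check_stationarity",
    "gc_magnitude",
    "gc_pair",
    "lags_to_seconds",
]

#: shortest admissible sample beyond the lag order
_MIN_EXTRA = 10


@dataclass(frozen=True)
class VarModel:
    """A fitted (vector) autoregression.

    coeffs has shape (p, n, n): ``coeffs[k][i, j]`` multiplies series j at
    lag k+1 in the equation for series i.  resid_var is the ML residual
    (co)variance, shape (n, n); n_effective = series length - p.
    """

    order: int
    coeffs: np.ndarray
    resid_var: np.ndarray
    n_effective: int
    degenerate: bool = False

    @property
    def n_series(self) -> int:
        return self.coeffs.shape[1]


@dataclass(frozen=True)
class GcEstimate:
    """Directed Granger-causality magnitude for one ordered pair."""

    source: str
    target: str
    order: int
    value: float
    degenerate: bool = False
    stationary: bool = True
    spectral_radius: float = float("nan")


def _as_matrix(series) -> np.ndarray:
    """Stack one or more aligned sequences into an (N, n) column matrix."""
    if isinstance(series, np.ndarray) and series.ndim == 2:
        return np.asarray(series, dtype=float)
    if isinstance(series, (tuple, list)) and len(series) in (1, 2) and np.ndim(series[0]) == 1:
        cols = [np.asarray(s, dtype=float) for s in series]
        if len({c.size for c in cols}) != 1:
            raise ValueError("series must be aligned and of equal length")
        return np.column_stack(cols)
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        return arr[:, None]
    raise ValueError("series must be one or two aligned 1-D sequences")


def _lagged_design(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response rows Y[t] and regressors [Y[t-1], ..., Y[t-p]] for t >= p."""
    n_obs, n = data.shape
    y = data[p:]
    x = np.empty((n_obs - p, n * p))
    for k in range(1, p + 1):
        x[:, (k - 1) * n : k * n] = data[p - k : n_obs - k]
    return y, x


def fit_var_ols(series, order: int) -> VarModel:
    """Fit a VAR(p) (or AR(p) for a single series) by per-equation OLS.

    Series are demeaned before fitting (equivalent to including an
    intercept).  Residual (co)variance uses the ML divisor n_effective.
    A rank-deficient regressor matrix flags the fit as degenerate.
    """
    data = _as_matrix(series)
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    n_obs, n = data.shape
    if n_obs <= p + _MIN_EXTRA:
        raise ValueError(f"series length {n_obs} too short for order {p}")
    data = data - data.mean(axis=0)
    y, x = _lagged_design(data, p)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    degenerate = rank < x.shape[1]
    resid = y - x @ beta
    n_eff = y.shape[0]
    sigma = resid.T @ resid / n_eff
    coeffs = beta.reshape(p, n, n).transpose(0, 2, 1)
    return VarModel(
        order=p,
        coeffs=coeffs,
        resid_var=sigma,
        n_effective=n_eff,
        degenerate=degenerate,
    )


def _aic(model: VarModel) -> float:
    """AIC for an n-variate VAR(p): ln det(Sigma) + 2 p n^2 / n_effective."""
    n = model.n_series
    sign, logdet = np.linalg.slogdet(np.atleast_2d(model.resid_var))
    if sign <= 0:
        return np.inf
    return logdet + 2.0 * model.order * n * n / model.n_effective


def aic_order_search(series, p_max: int = 20) -> int:
    """Smallest AIC-minimising order p in {1, ..., p_max}; ties go low."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    best_p, best_aic = 1, np.inf
    for p in range(1, p_max + 1):
        aic = _aic(fit_var_ols(series, p))
        if aic < best_aic - 1e-12:
            best_p, best_aic = p, aic
    return best_p


def select_participant_order(per_trial_orders: Sequence[int]) -> int:
    """Maximum per-trial AIC order: the single order reused for all trials."""
    orders = list(per_trial_orders)
    if not orders:
        raise ValueError("need at least one per-trial order")
    if any(int(p) < 1 for p in orders):
        raise ValueError("orders must be positive integers")
    return int(max(orders))


def check_stationarity(model: VarModel, tol: float = 1e-6) -> tuple[bool, float]:
    """Companion-matrix stability check.

    Returns (stationary, spectral_radius): the process is covariance-
    stationary iff every companion-matrix eigenvalue has modulus < 1.
    """
    p, n = model.order, model.n_series
    companion = np.zeros((n * p, n * p))
    for k in range(p):
        companion[:n, k * n : (k + 1) * n] = model.coeffs[k]
    if p > 1:
        companion[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    radius = float(np.max(np.abs(np.linalg.eigvals(companion))))
    return radius < 1.0 - tol, radius


def _affinely_identical(x: np.ndarray, y: np.ndarray) -> bool:
    """True when y = a + b*x exactly (within numerical tolerance)."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return True
    return bool(abs(float(xc @ yc) / (nx * ny)) > 1.0 - 1e-10)


def gc_magnitude(x, y, order: int, source: str = "x", target: str = "y") -> GcEstimate:
    """Granger-causality magnitude F_{x->y} at the given lag order.

    Affinely identical inputs (including exact copies) return F = 0 with
    the degenerate flag set — two identical series carry no incremental
    information about each other.  A non-stationary fitted VAR warns and
    annotates the estimate rather than aborting.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be aligned 1-D sequences")
    p = int(order)
    if xv.size <= p + _MIN_EXTRA:
        raise ValueError(f"series length {xv.size} too short for order {p}")
    if _affinely_identical(xv, yv):
        return GcEstimate(source=source, target=target, order=p, value=0.0, degenerate=True)
    full = fit_var_ols((xv, yv), p)
    reduced = fit_var_ols(yv, p)
    stationary, radius = check_stationarity(full)
    if not stationary:
        warnings.warn(
            f"VAR({p}) fit is non-stationary (spectral radius {radius:.4f}); "
            "GC magnitude may be unreliable",
            stacklevel=2,
        )
    sigma_full = float(full.resid_var[1, 1])
    sigma_reduced = float(reduced.resid_var[0, 0])
    if sigma_full <= 0.0 or full.degenerate:
        return GcEstimate(
            source=source, target=target, order=p, value=0.0,
            degenerate=True, stationary=stationary, spectral_radius=radius,
        )
    value = max(0.0, float(np.log(sigma_reduced / sigma_full)))
    return GcEstimate(
        source=source, target=target, order=p, value=value,
        stationary=stationary, spectral_radius=radius,
    )


def gc_pair(recording, performance, order: int) -> tuple[GcEstimate, GcEstimate]:
    """GC in both directions for one trial: (rec->perf, perf->rec)."""
    rec = getattr(recording, "values", recording)
    perf = getattr(performance, "values", performance)
    fwd = gc_magnitude(rec, perf, order, source="recording", target="performance")
    rev = gc_magnitude(perf, rec, order, source="performance", target="recording")
    return fwd, rev


def lags_to_seconds(order: float, interval: float = 0.125) -> float:
    """Convert a (possibly fractional mean) lag order to seconds of history."""
    return float(order) * float(interval)
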