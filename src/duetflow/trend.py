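"""Trial-wise trend inference for per-trial connectivity measures.

The study design is a small balanced repeated-measures layout: P
participants each contribute J consecutive trials of one measure (a GC
magnitude, a similarity coefficient, ...).  Inference follows three
routes:

* a paired t test comparing the two GC directions over participant x
  trial pairs;
* a random-intercept linear mixed model, value ~ 1 + trial + (1 |
  participant), fitted by maximum likelihood (not REML) so that the full
  model (with the trial slope) and the reduced model (intercept only)
  can be compared with a likelihood-ratio test on chi^2(1); the ML fit
  profiles the likelihood over the variance ratio sigma_b^2 / sigma_e^2,
  which is exact for this model class and fast enough for large
  simulation studies;
* an order-1 orthogonal-polynomial contrast across the J trial levels,
  tested against the within-participant residual (df = N - P), which for
  an 8 x 8 design yields the conventional F(1, 56).

The semi-partial R^2 of the trial effect is reported as the
proportional reduction in ML residual variance from the reduced to the
full model: 0 when the slope estimate is 0, approaching 1 as the trial
trend absorbs all within-participant variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MixedFit",
    "TrendFit",
    "PairedTestResult",
    "ContrastResult",
    "paired_direction_test",
    "fit_random_intercept_ml",
    "lrt_fixed_effect",
    "semipartial_r2",
    "trial_trend",
    "linear_trend_contrast",
]


@dataclass(frozen=True)
class MixedFit:
    """One ML fit of a random-intercept model y ~ X beta + b_g + e."""

    beta: np.ndarray           # fixed effects: intercept [, trial slope]
    sigma_participant2: float  # between-participant variance
    sigma_resid2: float        # residual variance
    loglik: float
    n_obs: int
    has_trial: bool

    @property
    def slope(self) -> float:
        if not self.has_trial:
            return 0.0
        return float(self.beta[1])


@dataclass(frozen=True)
class TrendFit:
    """Summary of the full-vs-reduced mixed-model comparison for one measure."""

    slope: float
    r2_semipartial: float
    lrt_stat: float
    p_value: float
    sigma_participant2: float
    sigma_resid2: float
    full: MixedFit
    reduced: MixedFit


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContrastResult:
    F_stat: float
    df_num: int
    df_den: int
    p_value: float


def paired_direction_test(a, b) -> PairedTestResult:
    """One-sample t test on paired differences a - b (two-sided).

    Pairs are participant x trial observations; df = n_pairs - 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise ValueError("paired differences have zero variance")
    n = diff.size
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTestResult(t_stat=t, df=n - 1, p_value=p)


def _extract_columns(
    table: pd.DataFrame, measure: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pull (value, trial, participant) arrays from a long-format table."""
    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
        if df.empty:
            raise ValueError(f"no rows for measure {measure!r}")
    value_col = "value" if "value" in df.columns else measure
    if value_col is None or value_col not in df.columns:
        raise ValueError("table needs a 'value' column (or a column named after the measure)")
    return (
        df[value_col].to_numpy(dtype=float),
        df["trial"].to_numpy(dtype=float),
        df["participant"].to_numpy(),
    )


def _profile_loglik(lam: float, y_g, x_g) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood at variance ratio lam = sigma_b^2/sigma_e^2.

    Uses the closed-form inverse (I + lam J)^-1 = I - lam/(1+n lam) J per
    group, and profiles out beta (GLS) and sigma_e^2 (ML divisor N).
    """
    xtx = 0.0
    xty = 0.0
    for y, x in zip(y_g, x_g):
        n_g = y.size
        shrink = lam / (1.0 + n_g * lam)
        xs = x.sum(axis=0)
        xtx = xtx + x.T @ x - shrink * np.outer(xs, xs)
        xty = xty + x.T @ y - shrink * xs * y.sum()
    beta = np.linalg.solve(xtx, xty)
    n_total = sum(y.size for y in y_g)
    quad = 0.0
    logdet = 0.0
    for y, x in zip(y_g, x_g):
        n_g = y.size
        r = y - x @ beta
        shrink = lam / (1.0 + n_g * lam)
        quad += r @ r - shrink * r.sum() ** 2
        logdet += np.log1p(n_g * lam)
    sigma2 = max(quad / n_total, 1e-300)
    ll = -0.5 * (n_total * (np.log(2.0 * np.pi) + 1.0 + np.log(sigma2)) + logdet)
    return float(ll), beta, float(sigma2)


def _fit_one(y: np.ndarray, x: np.ndarray, groups: np.ndarray, has_trial: bool) -> MixedFit:
    y_g, x_g = [], []
    for g in pd.unique(groups):
        mask = groups == g
        y_g.append(y[mask])
        x_g.append(x[mask])
    if len(y_g) < 2:
        raise ValueError("need at least two participants")
    if any(v.size < 2 for v in y_g):
        raise ValueError("need at least two trials per participant")

    def neg_ll_log(theta: float) -> float:
        return -_profile_loglik(np.exp(theta), y_g, x_g)[0]

    res = optimize.minimize_scalar(neg_ll_log, bounds=(-16.0, 16.0), method="bounded")
    ll_opt = -res.fun
    ll_zero, _, _ = _profile_loglik(0.0, y_g, x_g)
    lam = float(np.exp(res.x)) if ll_opt > ll_zero else 0.0
    ll, beta, sigma2 = _profile_loglik(lam, y_g, x_g)
    return MixedFit(
        beta=beta,
        sigma_participant2=lam * sigma2,
        sigma_resid2=sigma2,
        loglik=ll,
        n_obs=y.size,
        has_trial=has_trial,
    )


def fit_random_intercept_ml(
    table: pd.DataFrame, measure: str | None = None
) -> tuple[MixedFit, MixedFit]:
    """ML fits of the full (with trial slope) and reduced (intercept-only)
    random-intercept models on a long-format trial table.

    The table needs columns ``participant``, ``trial`` and ``value`` (or,
    for a long multi-measure table, a ``measure`` column filtered by the
    ``measure`` argument).  Trial enters as a numeric covariate.
    """
    y, trial, groups = _extract_columns(table, measure)
    x_full = np.column_stack([np.ones_like(y), trial])
    x_reduced = np.ones_like(y)[:, None]
    full = _fit_one(y, x_full, groups, has_trial=True)
    reduced = _fit_one(y, x_reduced, groups, has_trial=False)
    return full, reduced


def lrt_fixed_effect(full: MixedFit, reduced: MixedFit) -> tuple[float, float]:
    """Likelihood-ratio test of the trial slope: 2(ll_full - ll_reduced)
    referred to chi^2(1)."""
    if not (full.has_trial and not reduced.has_trial):
        raise ValueError("expected a full fit with trial and a reduced fit without")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on identical data")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(stats.chi2.sf(stat, df=1))


def semipartial_r2(full: MixedFit, reduced: MixedFit) -> float:
    """Proportion of residual variance explained by the trial effect.

    Computed as the proportional reduction in ML residual variance from
    the reduced to the full model, clipped to [0, 1].
    """
    if reduced.sigma_resid2 <= 0.0:
        return 0.0
    r2 = 1.0 - full.sigma_resid2 / reduced.sigma_resid2
    return float(np.clip(r2, 0.0, 1.0))


def trial_trend(table: pd.DataFrame, measure: str | None = None) -> TrendFit:
    """Convenience wrapper: fit both models and assemble the trend summary."""
    full, reduced = fit_random_intercept_ml(table, measure)
    stat, p = lrt_fixed_effect(full, reduced)
    return TrendFit(
        slope=full.slope,
        r2_semipartial=semipartial_r2(full, reduced),
        lrt_stat=stat,
        p_value=p,
        sigma_participant2=full.sigma_participant2,
        sigma_resid2=full.sigma_resid2,
        full=full,
        reduced=reduced,
    )


def linear_trend_contrast(table: pd.DataFrame, measure: str | None = None) -> ContrastResult:
    """Order-1 orthogonal-polynomial contrast across the trial levels.

    Requires a complete P x J design.  The contrast sum of squares (1 df)
    is tested against the within-participant residual, SS_total -
    SS_participant with df = N - P, so an 8 x 8 design yields F(1, 56).
    For 8 levels the weights are proportional to [-7, -5, -3, -1, +1,
    +3, +5, +7].
    """
    y, trial, groups = _extract_columns(table, measure)
    cell = pd.DataFrame({"participant": groups, "trial": trial.astype(int), "value": y})
    wide = cell.pivot_table(index="participant", columns="trial", values="value")
    if wide.isna().any().any():
        raise ValueError("incomplete design: every participant needs every trial")
    data = wide.to_numpy()
    n_part, n_trials = data.shape
    levels = np.arange(1, n_trials + 1, dtype=float)
    weights = levels - levels.mean()
    trial_means = data.mean(axis=0)
    contrast = float(weights @ trial_means)
    ss_linear = n_part * contrast**2 / float(weights @ weights)
    grand = data.mean()
    ss_participant = n_trials * float(((data.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    df_den = n_part * n_trials - n_part
    ss_error = max(ss_total - ss_participant, 0.0)
    if ss_error <= 0.0:
        return ContrastResult(F_stat=0.0, df_num=1, df_den=df_den, p_value=1.0)
    f = ss_linear / (ss_error / df_den)
    return ContrastResult(
        F_stat=float(f),
        df_num=1,
        df_den=int(df_den),
        p_value=float(stats.f.sf(f, 1, df_den)),
    )
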