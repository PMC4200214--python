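"""Lung clearance kinetics: single-phase linear fit of retained burden.

The retained particle mass in the lung after an inhalation exposure is
fitted with a zero-order (linear) model m(t) = m₀ − k·t, the model that
matches a single-phase linear clearance finding.  A first-order exponential
alternative m(t) = m₀·exp(−λt) is fitted alongside for model comparison
(AIC under i.i.d. Gaussian residuals) but is never the default.  The fitted
rate is reported both absolutely (μg/h) and normalized to the deposited
dose (%/day = rate × 24 / intercept × 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["RetentionSeries", "ClearanceFit", "fit_linear_clearance", "retained_mass"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetentionSeries:
    """Retained lung burden over time: hours post exposure vs mass (μg),
    with optional per-timepoint SD and group size."""

    times_h: np.ndarray
    mass_ug: np.ndarray
    sd_ug: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        m = np.asarray(self.mass_ug, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "mass_ug", m)
        if t.shape != m.shape or t.ndim != 1:
            raise ValueError("times_h and mass_ug must be 1-D and equal length")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("times_h must be sorted and non-negative")
        if np.any(m < 0):
            raise ValueError("mass_ug must be >= 0")


@dataclass
class ClearanceFit:
    """Fitted clearance line and goodness-of-fit summary.

    rate_ug_per_h is positive for physical clearance (mass decreasing);
    normalized_rate_pct_per_day = rate × 24 / intercept × 100.
    """

    intercept_ug: float
    rate_ug_per_h: float
    normalized_rate_pct_per_day: float
    r_squared: float
    aic_linear: float
    aic_exponential: float | None = None
    flags: list = field(default_factory=list)


def _aic(residuals: np.ndarray, n_params: int) -> float:
    n = len(residuals)
    rss = float(np.sum(residuals**2))
    # Gaussian log-likelihood with MLE variance
    return n * np.log(max(rss, 1e-300) / n) + 2 * n_params


def fit_linear_clearance(series: RetentionSeries, *, weighted: bool = False) -> ClearanceFit:
    """Ordinary least-squares fit of m(t) = m₀ − k·t.

    Requires >= 3 timepoints.  A negative fitted clearance rate (apparent
    growth) is flagged, never clamped.  With ``weighted`` and per-point SDs,
    weights 1/SD² are used instead of OLS.
    """
    t, m = series.times_h, series.mass_ug
    if len(t) < 3:
        raise ValueError(f"need >= 3 timepoints to fit clearance, got {len(t)}")
    if weighted and series.sd_ug is not None:
        w = 1.0 / np.asarray(series.sd_ug, dtype=float) ** 2
    else:
        w = np.ones_like(t)
    design = np.column_stack([np.ones_like(t), t])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], m * sw, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    rate = -slope
    flags: list[str] = []
    if rate < 0:
        flags.append("fitted rate is negative (apparent growth); not clamped")
        logger.warning("clearance fit returned a negative rate (%.4g ug/h)", rate)

    fitted = intercept + slope * t
    resid = m - fitted
    ss_tot = float(np.sum((m - np.mean(m)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    aic_lin = _aic(resid, 2)
    aic_exp = None
    try:
        popt, _ = curve_fit(
            lambda tt, m0, lam: m0 * np.exp(-lam * tt),
            t,
            m,
            p0=[max(intercept, 1e-6), max(rate, 1e-6) / max(intercept, 1e-6)],
            maxfev=10_000,
        )
        aic_exp = _aic(m - popt[0] * np.exp(-popt[1] * t), 2)
    except RuntimeError:
        flags.append("exponential alternative failed to converge")

    normalized = rate * 24.0 / intercept * 100.0 if intercept > 0 else float("nan")
    return ClearanceFit(
        intercept_ug=intercept,
        rate_ug_per_h=rate,
        normalized_rate_pct_per_day=normalized,
        r_squared=r2,
        aic_linear=aic_lin,
        aic_exponential=aic_exp,
        flags=flags,
    )


def retained_mass(fit: ClearanceFit, time_h: float) -> float:
    """Predicted retained mass max(0, m₀ − k·t); clamping at 0 is logged."""
    if time_h < 0:
        raise ValueError("time_h must be >= 0")
    value = fit.intercept_ug - fit.rate_ug_per_h * time_h
    if value < 0:
        logger.warning(
            "predicted retention negative at t=%.1f h; clamped to 0", time_h
        )
        return 0.0
    return value
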