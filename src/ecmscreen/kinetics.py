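"""Exponential growth-rate extraction from live-cell count time series.

The model is N(t) = N0 * exp(r t); (N0, r) are found by unweighted
nonlinear least squares on the raw counts using the Levenberg-Marquardt
algorithm, initialized from the first count and the log-linear OLS slope.
Rates are unconstrained in sign (drug-treated populations may shrink).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .types import GrowthCurve

__all__ = ["FitConfig", "GrowthFit", "fit_exponential", "fit_exponential_log", "relative_growth_rate"]


@dataclass
class FitConfig:
    """Optimizer settings: iteration budget and relative-change tolerance."""

    max_iter: int = 500
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class GrowthFit:
    """Fitted exponential: initial count, rate (1/h), uncertainty, fit quality."""

    n0_hat: float
    rate_hat: float
    rate_se: float
    rss: float
    converged: bool
    n_iter: int
    condition: dict | None = None


def _init_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n0 = max(float(y[0]), 1.0)
    logy = np.log(np.clip(y, 1.0, None))
    slope = np.polyfit(t, logy, 1)[0]
    return n0, float(slope)


def fit_exponential(curve: GrowthCurve, config: FitConfig | None = None) -> GrowthFit:
    """Fit N(t) = N0 exp(r t) to a growth curve by Levenberg-Marquardt.

    Minimizes the unweighted residual sum of squares on raw counts.
    ``rate_se`` is the standard error from the fit covariance (0 when the
    covariance is unavailable, e.g. an exact noiseless fit). ``converged``
    requires both optimizer success and no worsening of the RSS relative
    to the initialization.
    """
    cfg = config or FitConfig()
    t = np.asarray(curve.times, float)
    y = np.asarray(curve.counts, float)
    if len(t) < 3:
        raise ValueError(f"need >= 3 timepoints to fit, got {len(t)}")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise ValueError("non-finite values in growth curve")
    if np.all(y == 0):
        raise ValueError("all counts are zero; nothing to fit")

    n0_init, r_init = _init_guess(t, y)
    rss_init = float(np.sum((y - n0_init * np.exp(r_init * t)) ** 2))

    params = lmfit.Parameters()
    params.add("n0", value=n0_init, min=1e-12)
    params.add("r", value=r_init)

    def resid(p: lmfit.Parameters) -> np.ndarray:
        return y - p["n0"].value * np.exp(p["r"].value * t)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(
            resid,
            params,
            method="leastsq",
            xtol=cfg.tolerance,
            ftol=cfg.tolerance,
            max_nfev=cfg.max_iter * 3,
        )
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    se = out.params["r"].stderr
    return GrowthFit(
        n0_hat=float(out.params["n0"].value),
        rate_hat=float(out.params["r"].value),
        rate_se=float(se) if se is not None and np.isfinite(se) else 0.0,
        rss=rss,
        converged=bool(out.success) and rss <= rss_init + 1e-12,
        n_iter=int(out.nfev),
        condition=dict(curve.condition) if curve.condition else None,
    )


def fit_exponential_log(curve: GrowthCurve) -> GrowthFit:
    """Log-space fallback: OLS of ln(counts) vs time on positive counts.

    Useful for curves containing zeros or spanning decades; the rate is
    the OLS slope, N0 the exponentiated intercept.
    """
    t = np.asarray(curve.times, float)
    y = np.asarray(curve.counts, float)
    keep = y > 0
    if keep.sum() < 3:
        raise ValueError("need >= 3 positive counts for the log-space fit")
    t, y = t[keep], y[keep]
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    slope, intercept = coef
    n = len(t)
    resid = np.log(y) - A @ coef
    s2 = float(resid @ resid) / max(n - 2, 1)
    se = float(np.sqrt(s2 / np.sum((t - t.mean()) ** 2))) if n > 2 else 0.0
    n0 = float(np.exp(intercept))
    rss = float(np.sum((y - n0 * np.exp(slope * t)) ** 2))
    return GrowthFit(
        n0_hat=n0,
        rate_hat=float(slope),
        rate_se=se,
        rss=rss,
        converged=True,
        n_iter=1,
        condition=dict(curve.condition) if curve.condition else None,
    )


def relative_growth_rate(treated: GrowthFit, control: GrowthFit) -> float:
    """Treated rate divided by matched untreated rate (dimensionless).

    May be <= 0 for cytotoxic doses. Undefined when the control rate is
    not positive.
    """
    if not control.rate_hat > 0:
        raise ValueError(
            f"relative growth rate undefined: control rate {control.rate_hat:.4g} <= 0"
        )
    return treated.rate_hat / control.rate_hat
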