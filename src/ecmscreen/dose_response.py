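"""Dose-response curves and IC50 by linear interpolation on log concentration.

The IC50 is defined operationally as the drug concentration at which the
growth rate is 50% of the untreated value. Relative rates are computed
against the dose-0 control of the same condition, and the crossing of 0.5
is located by linear interpolation of relative rate against log10(dose)
between the first adjacent bracketing pair of positive doses. Dose 0 only
anchors the normalization; it never enters the log axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .kinetics import GrowthFit, relative_growth_rate

__all__ = ["DoseResponseCurve", "IC50Estimate", "build_curve", "ic50_log_interp"]


@dataclass
class DoseResponseCurve:
    """Relative growth rate at each dose of a dilution ladder (dose 0 = 1)."""

    doses: np.ndarray
    rel_rates: np.ndarray
    condition: dict | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.rel_rates = np.asarray(self.rel_rates, float)
        if self.doses.shape != self.rel_rates.shape:
            raise ValueError("doses and rel_rates must have equal length")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.doses[0] != 0:
            raise ValueError("curve must include dose 0 as the untreated anchor")
        if abs(self.rel_rates[0] - 1.0) > 1e-6:
            raise ValueError(
                f"relative rate at dose 0 must equal 1, got {self.rel_rates[0]:.6g}"
            )


@dataclass
class IC50Estimate:
    """IC50 in uM, or the censoring direction when 0.5 is never crossed."""

    value: float | None
    censored: Literal["none", "above_max", "below_min"]
    bracket: tuple[float, float] | None = None


def build_curve(fits_by_dose: Mapping[float, GrowthFit], condition: dict | None = None) -> DoseResponseCurve:
    """Assemble a relative-rate curve from per-dose exponential fits.

    Every rate is divided by the dose-0 control fit of the same
    condition/replicate; the control must be present with a positive rate.
    """
    doses = sorted(float(d) for d in fits_by_dose)
    if not doses or doses[0] != 0.0:
        raise ValueError("missing untreated (dose 0) control fit")
    control = fits_by_dose[0.0 if 0.0 in fits_by_dose else 0]
    rel = np.array([relative_growth_rate(fits_by_dose[d], control) for d in doses])
    rel[0] = 1.0
    return DoseResponseCurve(np.array(doses), rel, condition=condition)


def ic50_log_interp(curve: DoseResponseCurve) -> IC50Estimate:
    """Locate the 0.5 crossing by linear interpolation on a log10 dose axis.

    Positive doses are scanned in increasing order for the first adjacent
    pair (d_a, d_b) with rel(d_a) >= 0.5 >= rel(d_b); within the pair,
    log10(IC50) = log10(d_a) + (rel_a - 0.5)/(rel_a - rel_b) *
    (log10(d_b) - log10(d_a)). An exact hit returns that dose. Curves
    that never reach 0.5 are censored ``above_max``; curves already below
    0.5 at the lowest positive dose are censored ``below_min``. Negative
    relative rates participate unchanged (they are simply below 0.5).
    """
    pos = curve.doses > 0
    d = curve.doses[pos]
    r = curve.rel_rates[pos]
    if len(d) < 2:
        raise ValueError("need >= 2 positive doses for interpolation")
    if r[0] < 0.5:
        return IC50Estimate(value=None, censored="below_min")
    for i in range(len(d)):
        if r[i] == 0.5:
            return IC50Estimate(value=float(d[i]), censored="none", bracket=(float(d[i]), float(d[i])))
        if i + 1 < len(d) and r[i] >= 0.5 > r[i + 1]:
            la, lb = np.log10(d[i]), np.log10(d[i + 1])
            frac = (r[i] - 0.5) / (r[i] - r[i + 1])
            return IC50Estimate(
                value=float(10 ** (la + frac * (lb - la))),
                censored="none",
                bracket=(float(d[i]), float(d[i + 1])),
            )
    return IC50Estimate(value=None, censored="above_max")
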