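"""Comparative statistics for the screening analysis.

Four procedures: an exact two-sided sign test for monotone trends across
ordered oxygen levels; a hierarchical Bayesian model of growth rates with
fixed cell-type and plate-type effects, a random experiment-date effect
and plate-type-grouped residual variances; an empirical Bayesian model of
log-IC50 differences between hypoxia and normoxia reported as fold
changes; and two-sided Welch t-tests.

The Bayesian models put zero-centered Cauchy priors on coefficients and
half-Cauchy priors on standard deviations ("Cauchy priors on variances"
is realized on the SD scale, where the distribution is proper), with
widths defaulting to 10x the empirical SD of the response — weakly
informative, scaled loosely to the data. Posteriors are drawn with the
adaptive Metropolis-within-Gibbs sampler in :mod:`ecmscreen.sampler`,
augmented with two reparameterization block moves (a mean/random-effect
ridge shift and a scale/effect funnel rescale) that decorrelate the
intercept and the experiment-level scale, and gated on split-R-hat < 1.05
and ESS > 400 per reported parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sampler import ess, rhat, sample_mwg

__all__ = [
    "SignTestResult",
    "WelchResult",
    "HierarchicalModelSpec",
    "PosteriorSummary",
    "sign_test_two_sided",
    "welch_t_test",
    "fit_hierarchical_growth_model",
    "fit_ic50_difference_model",
]


# ---------------------------------------------------------------------------
# exact sign test
# ---------------------------------------------------------------------------


@dataclass
class SignTestResult:
    n: int  # non-tied pairs
    k: int  # pairs in the positive direction
    p_two_sided: float


def sign_test_two_sided(deltas: Sequence[float]) -> SignTestResult:
    """Exact two-sided sign test on the signs of paired differences.

    Ties (zero differences) are dropped; with X ~ Binomial(n, 1/2),
    p = min(1, 2 * min(P(X <= k), P(X >= k))) by exact summation of
    binomial tail probabilities.
    """
    d = np.asarray(list(deltas), float)
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        raise ValueError("all differences are ties; the sign test is undefined")
    k = int((d > 0).sum())
    half = 0.5**n
    lower = sum(math.comb(n, i) for i in range(0, k + 1)) * half
    upper = sum(math.comb(n, i) for i in range(k, n + 1)) * half
    p = min(1.0, 2.0 * min(lower, upper))
    return SignTestResult(n=n, k=k, p_two_sided=float(p))


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------


@dataclass
class WelchResult:
    t: float
    df: float
    p_two_sided: float


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise ValueError("degenerate variance: both groups are constant")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p_two_sided=float(p))


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Posterior means, symmetric 95% credible intervals and diagnostics."""

    summary: pd.DataFrame  # index parameter; mean, ci_lo, ci_hi, rhat, ess
    samples: dict[str, np.ndarray] = field(default_factory=dict)  # (chains, draws)
    converged: bool = True

    def __getitem__(self, name: str) -> pd.Series:
        return self.summary.loc[name]


def _summarize(
    named_draws: dict[str, np.ndarray], gate_rhat: float = 1.05, gate_ess: float = 400.0
) -> PosteriorSummary:
    rows = {}
    ok = True
    for name, arr in named_draws.items():
        flat = arr.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        if np.ptp(arr) == 0:  # pinned parameter (e.g. reference level)
            r, e = 1.0, float(flat.size)
        else:
            r, e = rhat(arr), ess(arr)
        rows[name] = {
            "mean": float(flat.mean()),
            "ci_lo": float(lo),
            "ci_hi": float(hi),
            "rhat": r,
            "ess": e,
        }
        if not (np.isfinite(r) and r < gate_rhat and e > gate_ess):
            ok = False
    df = pd.DataFrame(rows).T[["mean", "ci_lo", "ci_hi", "rhat", "ess"]]
    return PosteriorSummary(summary=df, samples=named_draws, converged=ok)


# ---------------------------------------------------------------------------
# hierarchical Bayesian growth-rate model
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalModelSpec:
    """Model columns, prior widths and sampler settings.

    ``prior_scale_mult`` sets the Cauchy / half-Cauchy widths to this
    multiple of the empirical SD of the response ("scaled loosely to the
    data"). ``contrasts`` lists (factor, level_a, level_b) requests whose
    posterior difference beta[level_a] - beta[level_b] is summarized,
    with factor one of "cell" or "plate".
    """

    response: str = "rate"
    cell_col: str = "cell"
    plate_col: str = "plate"
    experiment_col: str = "experiment"
    prior_scale_mult: float = 10.0
    contrasts: tuple[tuple[str, str, str], ...] = ()
    chains: int = 4
    warmup: int = 500
    draws: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_scale_mult <= 0:
            raise ValueError("prior widths must be > 0")
        if self.chains < 2:
            raise ValueError("need >= 2 chains")


class HierarchicalGrowthModel:
    """y = mu + beta_cell + beta_plate + sigma_exp*z_experiment + eps.

    Reference-level coding (first level alphabetically pinned to 0)
    identifies the fixed effects; the experiment effect is sampled
    non-centered. The residual SD is per plate type. The unconstrained
    parameter vector is

        [mu | beta_cell[1:] | beta_plate[1:] | z[E] | log sigma_exp | log sigma_plate[P]]

    and :meth:`make_logpost` binds a response matrix with one row per
    sampler chain, so many simulated datasets can be fitted in a single
    vectorized run.
    """

    def __init__(self, ci: np.ndarray, pi: np.ndarray, ei: np.ndarray,
                 C: int, P: int, E: int, prior_width: float):
        self.ci, self.pi, self.ei = ci, pi, ei
        self.C, self.P, self.E = C, P, E
        self.w = prior_width
        self.i_mu = 0
        self.i_bc = slice(1, C)
        self.i_bp = slice(C, C + P - 1)
        self.i_z = slice(C + P - 1, C + P - 1 + E)
        self.i_lse = C + P - 1 + E
        self.i_lsp = slice(C + P + E, C + P + E + P)
        self.dim = C + P + E + P

    def make_logpost(self, Y: np.ndarray):
        """Log posterior for a (rows, n) response matrix (rows may be 1)."""
        ci, pi, ei, w = self.ci, self.pi, self.ei, self.w
        i_bc, i_bp, i_z, i_lse, i_lsp = self.i_bc, self.i_bp, self.i_z, self.i_lse, self.i_lsp

        def logpost(X: np.ndarray) -> np.ndarray:
            rows = X.shape[0]
            bc = np.concatenate([np.zeros((rows, 1)), X[:, i_bc]], axis=1)
            bp = np.concatenate([np.zeros((rows, 1)), X[:, i_bp]], axis=1)
            z = X[:, i_z]
            se = np.exp(X[:, i_lse])
            sp = np.exp(X[:, i_lsp])
            mean = X[:, [0]] + bc[:, ci] + bp[:, pi] + se[:, None] * z[:, ei]
            sig = sp[:, pi]
            resid = (Y - mean) / sig
            llik = -0.5 * np.einsum("ij,ij->i", resid, resid) - np.sum(np.log(sig), axis=1)
            coef = np.concatenate([X[:, [0]], X[:, i_bc], X[:, i_bp]], axis=1)
            lprior = -np.sum(np.log1p((coef / w) ** 2), axis=1)
            lprior -= 0.5 * np.einsum("ij,ij->i", z, z)
            # half-Cauchy on the scales, with the log-parameterization Jacobian
            lprior += -np.log1p((se / w) ** 2) + X[:, i_lse]
            lprior += np.sum(-np.log1p((sp / w) ** 2) + X[:, i_lsp], axis=1)
            return llik + lprior

        return logpost

    def block_moves(self):
        """Ridge and funnel reparameterization moves for mu / z / sigma_exp."""
        i_z, i_lse, E = self.i_z, self.i_lse, self.E

        def ridge(X: np.ndarray, step: np.ndarray, rng: np.random.Generator):
            # shift mu, compensate through the random effects: likelihood-invariant
            delta = step * rng.standard_normal(X.shape[0])
            Xp = X.copy()
            Xp[:, 0] += delta
            Xp[:, i_z] -= (delta / np.exp(X[:, i_lse]))[:, None]
            return Xp, np.zeros(X.shape[0])

        def funnel(X: np.ndarray, step: np.ndarray, rng: np.random.Generator):
            # rescale sigma_exp, compensate z so u = sigma_exp * z is unchanged
            delta = step * rng.standard_normal(X.shape[0])
            Xp = X.copy()
            Xp[:, i_lse] += delta
            Xp[:, i_z] *= np.exp(-delta)[:, None]
            return Xp, -E * delta

        return (ridge, funnel)

    def init_state(self, Y: np.ndarray, sd_y: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-row initial state and componentwise proposal scales."""
        rows = Y.shape[0]
        x0 = np.zeros((rows, self.dim))
        x0[:, 0] = Y.mean(axis=1)
        x0[:, self.i_lse] = math.log(max(sd_y * 0.5, 1e-12))
        x0[:, self.i_lsp] = math.log(max(sd_y * 0.5, 1e-12))
        scales = np.full(self.dim, 0.5)
        scales[0] = sd_y
        scales[self.i_bc] = sd_y
        scales[self.i_bp] = sd_y
        return x0, scales


def _check_levels(series: pd.Series, name: str) -> list[str]:
    levels = sorted(series.astype(str).unique())
    if len(levels) < 1:
        raise ValueError(f"factor {name} has no levels")
    return levels


def build_hierarchical_model(
    table: pd.DataFrame, spec: HierarchicalModelSpec
) -> tuple[HierarchicalGrowthModel, np.ndarray, dict[str, list[str]]]:
    """Index the factor levels of a growth-rate table and build the model."""
    for col in (spec.response, spec.cell_col, spec.plate_col, spec.experiment_col):
        if col not in table.columns:
            raise ValueError(f"table missing required column {col!r}")
    y = table[spec.response].to_numpy(float)
    cells = _check_levels(table[spec.cell_col], spec.cell_col)
    plates = _check_levels(table[spec.plate_col], spec.plate_col)
    exps = _check_levels(table[spec.experiment_col], spec.experiment_col)
    if len(exps) < 2:
        raise ValueError("need >= 2 experiments for the random experiment effect")
    ci = table[spec.cell_col].astype(str).map({l: i for i, l in enumerate(cells)}).to_numpy()
    pi = table[spec.plate_col].astype(str).map({l: i for i, l in enumerate(plates)}).to_numpy()
    ei = table[spec.experiment_col].astype(str).map({l: i for i, l in enumerate(exps)}).to_numpy()
    sd_y = float(np.std(y)) or 1.0
    model = HierarchicalGrowthModel(
        ci, pi, ei, len(cells), len(plates), len(exps), spec.prior_scale_mult * sd_y
    )
    return model, y, {"cell": cells, "plate": plates, "experiment": exps, "sd_y": sd_y}


def _hier_named_draws(
    S: np.ndarray, model: HierarchicalGrowthModel, levels: dict,
    contrasts: Sequence[tuple[str, str, str]],
) -> dict[str, np.ndarray]:
    cells, plates = levels["cell"], levels["plate"]
    C, P, E = model.C, model.P, model.E
    named: dict[str, np.ndarray] = {"mu": S[:, :, 0]}
    beta_cell = {cells[0]: np.zeros(S.shape[:2])}
    for j, lev in enumerate(cells[1:]):
        beta_cell[lev] = S[:, :, 1 + j]
        named[f"beta_cell[{lev}]"] = beta_cell[lev]
    beta_plate = {plates[0]: np.zeros(S.shape[:2])}
    for j, lev in enumerate(plates[1:]):
        beta_plate[lev] = S[:, :, C + j]
        named[f"beta_plate[{lev}]"] = beta_plate[lev]
    named["sigma_exp"] = np.exp(S[:, :, model.i_lse])
    for j, lev in enumerate(plates):
        named[f"sigma_resid[{lev}]"] = np.exp(S[:, :, C + P + E + j])
    for factor, la, lb in contrasts:
        table_map = {"cell": beta_cell, "plate": beta_plate}
        if factor not in table_map:
            raise ValueError(f"unknown contrast factor {factor!r}")
        betas = table_map[factor]
        for lev in (la, lb):
            if lev not in betas:
                raise ValueError(f"contrast level {lev!r} absent from factor {factor!r}")
        named[f"contrast[{factor}:{la}-{lb}]"] = betas[la] - betas[lb]
    return named


def fit_hierarchical_growth_model(
    table: pd.DataFrame, spec: HierarchicalModelSpec | None = None
) -> PosteriorSummary:
    """Fit y = mu + beta_cell + beta_plate + u_experiment + eps by MCMC.

    Returns posterior means, symmetric 95% credible intervals, split-R-hat
    and ESS for mu, the fixed effects, the scale parameters and any
    requested contrasts; ``converged`` is the joint R-hat/ESS gate.
    """
    spec = spec or HierarchicalModelSpec()
    model, y, levels = build_hierarchical_model(table, spec)
    Y = np.broadcast_to(y, (spec.chains, y.size))
    x0, scales = model.init_state(Y, levels["sd_y"])
    res = sample_mwg(
        model.make_logpost(Y),
        x0,
        n_chains=spec.chains,
        warmup=spec.warmup,
        draws=spec.draws,
        seed=spec.seed,
        init_scales=scales,
        block_moves=model.block_moves(),
    )
    named = _hier_named_draws(res.samples, model, levels, spec.contrasts)
    return _summarize(named)


# ---------------------------------------------------------------------------
# empirical Bayesian IC50-difference model
# ---------------------------------------------------------------------------


class IC50DifferenceModel:
    """log IC50 ~ N(alpha_cell + delta_{cell,hypoxia}, sigma^2).

    delta is zero for normoxia rows; priors are Gaussian on alpha and the
    differences delta, half-Cauchy on sigma. Parameter layout:
    [alpha[C] | delta[C*H] | log sigma].
    """

    def __init__(self, ci: np.ndarray, hi: np.ndarray, C: int, H: int, prior_width: float):
        self.ci, self.hi = ci, hi
        self.C, self.H = C, H
        self.w = prior_width
        self.dim = C + C * H + 1

    def make_logpost(self, Y: np.ndarray):
        ci, hi, C, H, w = self.ci, self.hi, self.C, self.H, self.w
        n = Y.shape[1]

        def logpost(X: np.ndarray) -> np.ndarray:
            rows = X.shape[0]
            alpha = X[:, :C]
            delta = X[:, C : C + C * H].reshape(rows, C, H)
            sig = np.exp(X[:, -1])
            dfull = np.concatenate([np.zeros((rows, C, 1)), delta], axis=2)
            mean = alpha[:, ci] + dfull[:, ci, hi]
            resid = (Y - mean) / sig[:, None]
            llik = -0.5 * np.einsum("ij,ij->i", resid, resid) - n * np.log(sig)
            lprior = -0.5 * np.sum((X[:, : C + C * H] / w) ** 2, axis=1)
            lprior += -np.log1p((sig / w) ** 2) + X[:, -1]
            return llik + lprior

        return logpost

    def init_state(self, Y: np.ndarray, sd: float) -> tuple[np.ndarray, np.ndarray]:
        rows = Y.shape[0]
        x0 = np.zeros((rows, self.dim))
        x0[:, : self.C] = Y.mean(axis=1)[:, None]
        x0[:, -1] = math.log(max(sd * 0.5, 1e-12))
        scales = np.full(self.dim, 0.5)
        scales[: self.C + self.C * self.H] = sd
        return x0, scales


def build_ic50_model(
    ic50_table: pd.DataFrame,
    *,
    normoxia: str = "21",
    ic50_col: str = "ic50_uM",
    cell_col: str = "cell",
    o2_col: str = "o2",
    prior_scale_mult: float = 10.0,
) -> tuple[IC50DifferenceModel, np.ndarray, dict]:
    """Validate an IC50 replicate table and build the difference model."""
    df = ic50_table.copy()
    bad = ~(df[ic50_col] > 0) | ~np.isfinite(df[ic50_col])
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive/censored IC50 values")
        df = df[~bad]
    df[o2_col] = df[o2_col].astype(str)
    if normoxia not in set(df[o2_col]):
        raise ValueError(f"normoxia level {normoxia!r} absent from {o2_col}")
    counts = df.groupby([cell_col, o2_col]).size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 replicates per (cell, O2) cell; short: {small}")
    cells = sorted(df[cell_col].astype(str).unique())
    hyp = [o for o in sorted(df[o2_col].unique(), key=float) if o != normoxia]
    logy = np.log(df[ic50_col].to_numpy(float))
    ci = df[cell_col].astype(str).map({l: i for i, l in enumerate(cells)}).to_numpy()
    hmap = {normoxia: 0, **{o: i + 1 for i, o in enumerate(hyp)}}
    hi = df[o2_col].map(hmap).to_numpy()
    sd = float(np.std(logy)) or 1.0
    model = IC50DifferenceModel(ci, hi, len(cells), len(hyp), prior_scale_mult * sd)
    return model, logy, {"cells": cells, "hypoxia": hyp, "normoxia": normoxia, "sd": sd}


def ic50_named_draws(S: np.ndarray, model: IC50DifferenceModel, levels: dict) -> dict[str, np.ndarray]:
    cells, hyp, normoxia = levels["cells"], levels["hypoxia"], levels["normoxia"]
    C, H = model.C, model.H
    named: dict[str, np.ndarray] = {"sigma": np.exp(S[:, :, -1])}
    for i, c in enumerate(cells):
        named[f"alpha[{c}]"] = S[:, :, i]
        for j, o in enumerate(hyp):
            d = S[:, :, C + i * H + j]
            named[f"delta[{c}:{o}-vs-{normoxia}]"] = d
            named[f"fold_change[{c}:{o}-vs-{normoxia}]"] = np.exp(d)
    return named


def fit_ic50_difference_model(
    ic50_table: pd.DataFrame,
    *,
    normoxia: str = "21",
    ic50_col: str = "ic50_uM",
    cell_col: str = "cell",
    o2_col: str = "o2",
    prior_scale_mult: float = 10.0,
    chains: int = 4,
    warmup: int = 500,
    draws: int = 1000,
    seed: int = 0,
) -> PosteriorSummary:
    """Model log-IC50 differences between hypoxia levels and normoxia.

    Per cell line c and hypoxia level h, the difference delta_{c,h} vs
    normoxia is reported both on the log scale and as a fold change
    exp(delta) with a symmetric 95% credible interval. Censored or
    non-positive IC50 inputs are excluded with a warning.
    """
    model, logy, levels = build_ic50_model(
        ic50_table, normoxia=normoxia, ic50_col=ic50_col, cell_col=cell_col,
        o2_col=o2_col, prior_scale_mult=prior_scale_mult,
    )
    Y = np.broadcast_to(logy, (chains, logy.size))
    x0, scales = model.init_state(Y, levels["sd"])
    res = sample_mwg(
        model.make_logpost(Y), x0, n_chains=chains, warmup=warmup, draws=draws,
        seed=seed, init_scales=scales,
    )
    return _summarize(ic50_named_draws(res.samples, model, levels))
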