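"""Simulation studies: calibration and parameter recovery of the Bayesian models.

Each study plants a known effect with the synthetic generators, fits the
corresponding model and reports per-simulation posterior summaries plus
coverage of the 95% credible interval. All simulated datasets share one
design, so the fits run as a single vectorized sampler call with
``n_sims * chains`` rows — the same model code and sampler as the
one-dataset fitting functions, batched.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._rng import substream
from .sampler import sample_mwg
from .stats import (
    HierarchicalModelSpec,
    build_hierarchical_model,
    build_ic50_model,
    ic50_named_draws,
)
from .synth import EffectsTableSpec, gen_effects_table

__all__ = ["hierarchical_contrast_coverage", "ic50_fold_recovery", "gen_ic50_replicates"]


def hierarchical_contrast_coverage(
    n_sims: int = 300,
    effects_spec: EffectsTableSpec | None = None,
    contrast: tuple[str, str, str] = ("plate", "Softwell 2 kPa", "Softwell 0.2 kPa"),
    *,
    chains: int = 2,
    warmup: int = 400,
    draws: int = 700,
    seed: int = 0,
) -> pd.DataFrame:
    """Credible-interval calibration of a planted fixed-effect contrast.

    Simulates ``n_sims`` growth-rate tables from ``effects_spec`` (default:
    the study-scale table with a true 2 kPa vs 0.2 kPa contrast of
    0.006/h), fits the hierarchical model to each, and returns one row per
    simulation with the posterior mean, the symmetric 95% CI and whether
    it covers the truth. At nominal 95%, coverage should land near 0.95.
    """
    base = effects_spec or EffectsTableSpec()
    factor, la, lb = contrast
    effects = {"cell": base.cell_effects, "plate": base.plate_effects}[factor]
    true_contrast = effects[la] - effects[lb]

    # all sims share the design; only the noise realizations differ
    tables = []
    for s in range(n_sims):
        sim_seed = int(substream(seed, "coverage", s).integers(2**31))
        table, _ = gen_effects_table(dataclasses.replace(base, seed=sim_seed))
        tables.append(table)
    spec = HierarchicalModelSpec(contrasts=(contrast,), chains=chains,
                                 warmup=warmup, draws=draws, seed=seed)
    model, _, levels = build_hierarchical_model(tables[0], spec)
    Y = np.repeat(
        np.stack([t["rate"].to_numpy(float) for t in tables]), chains, axis=0
    )  # rows ordered sim-major: (sim 0 chain 0, sim 0 chain 1, sim 1 chain 0, ...)
    x0, scales = model.init_state(Y, levels["sd_y"])
    res = sample_mwg(
        model.make_logpost(Y), x0, n_chains=Y.shape[0], warmup=warmup, draws=draws,
        seed=int(substream(seed, "coverage-mcmc").integers(2**31)),
        init_scales=scales, block_moves=model.block_moves(),
    )
    cells, plates = levels["cell"], levels["plate"]
    idx = {"cell": (1, cells), "plate": (model.C, plates)}[factor]
    offset, levs = idx

    def beta_col(lev: str) -> np.ndarray:
        j = levs.index(lev)
        if j == 0:
            return np.zeros(res.samples.shape[:2])
        return res.samples[:, :, offset + j - 1]

    diff = beta_col(la) - beta_col(lb)  # (n_sims*chains, draws)
    diff = diff.reshape(n_sims, chains * draws)
    lo, hi = np.percentile(diff, [2.5, 97.5], axis=1)
    out = pd.DataFrame(
        {
            "mean": diff.mean(axis=1),
            "ci_lo": lo,
            "ci_hi": hi,
            "true_contrast": true_contrast,
        }
    )
    out["covered"] = (out["ci_lo"] <= true_contrast) & (true_contrast <= out["ci_hi"])
    return out


def gen_ic50_replicates(
    *,
    base_ic50_uM: float = 0.3,
    fold_change: float = 1.7,
    hypoxia: str = "0.1",
    normoxia: str = "21",
    n_replicates: int = 6,
    noise_sd_log: float = 0.2,
    cell: str = "HCT116",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-experiment IC50 replicates with a planted hypoxia fold change.

    Replicate IC50s are lognormal around the group geometric mean — the
    noise model implied by analyzing IC50 differences on the log scale —
    with SD ``noise_sd_log`` on the log scale (about a 20% CV, a typical
    experiment-to-experiment spread for interpolated IC50s).
    """
    rng = substream(seed, "ic50-replicates")
    rows = []
    for o2, mu in ((normoxia, np.log(base_ic50_uM)),
                   (hypoxia, np.log(base_ic50_uM) + np.log(fold_change))):
        vals = np.exp(mu + noise_sd_log * rng.standard_normal(n_replicates))
        rows += [{"cell": cell, "o2": o2, "ic50_uM": v} for v in vals]
    return pd.DataFrame(rows)


def ic50_fold_recovery(
    n_sims: int = 100,
    *,
    fold_change: float = 1.7,
    base_ic50_uM: float = 0.3,
    n_replicates: int = 6,
    noise_sd_log: float = 0.2,
    chains: int = 2,
    warmup: int = 400,
    draws: int = 700,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery of a planted IC50 fold change across many simulated screens.

    Returns one row per simulation: posterior mean of the fold change
    exp(delta), its symmetric 95% CI, and whether the CI covers the true
    fold change.
    """
    tables = [
        gen_ic50_replicates(
            base_ic50_uM=base_ic50_uM, fold_change=fold_change,
            n_replicates=n_replicates, noise_sd_log=noise_sd_log,
            seed=int(substream(seed, "ic50-sim", s).integers(2**31)),
        )
        for s in range(n_sims)
    ]
    model, logy0, levels = build_ic50_model(tables[0])
    Y = np.repeat(
        np.stack([np.log(t["ic50_uM"].to_numpy(float)) for t in tables]), chains, axis=0
    )
    x0, scales = model.init_state(Y, levels["sd"])
    res = sample_mwg(
        model.make_logpost(Y), x0, n_chains=Y.shape[0], warmup=warmup, draws=draws,
        seed=int(substream(seed, "ic50-mcmc").integers(2**31)), init_scales=scales,
    )
    name = f"delta[{levels['cells'][0]}:{levels['hypoxia'][0]}-vs-{levels['normoxia']}]"
    delta = ic50_named_draws(res.samples, model, levels)[name]
    fold = np.exp(delta).reshape(n_sims, chains * draws)
    lo, hi = np.percentile(fold, [2.5, 97.5], axis=1)
    out = pd.DataFrame(
        {"mean_fold": fold.mean(axis=1), "ci_lo": lo, "ci_hi": hi, "true_fold": fold_change}
    )
    out["covered"] = (out["ci_lo"] <= fold_change) & (fold_change <= out["ci_hi"])
    return out
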