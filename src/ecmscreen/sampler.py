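"""Adaptive random-walk Metropolis-within-Gibbs sampler.

Componentwise Gaussian random-walk updates, vectorized across chains,
with per-chain, per-parameter proposal scales adapted toward a 0.44
acceptance rate by Robbins-Monro during warmup and frozen afterwards.
Models may add *block moves* — volume-tracked joint transformations such
as a mean/random-effect ridge shift or a scale/effect funnel rescale —
which are proposed once per sweep with their own adapted step size.
The deliverable of the models built on top is the converged posterior —
gated by split-R-hat and effective sample size — not the sampler brand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["MCMCResult", "BlockMove", "sample_mwg", "rhat", "ess"]

_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk updates
_TARGET_ACCEPT_BLOCK = 0.30


#: A block move maps (state matrix, per-row step, rng) to a proposed state
#: matrix plus a per-row log volume correction (log |Jacobian|).
BlockMove = Callable[[np.ndarray, np.ndarray, np.random.Generator], tuple[np.ndarray, np.ndarray]]


@dataclass
class MCMCResult:
    """Posterior draws of shape (chains, draws, dim) plus acceptance rates."""

    samples: np.ndarray
    accept_rate: np.ndarray  # per (chain, dim)


def sample_mwg(
    logpost: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    n_chains: int = 4,
    warmup: int = 500,
    draws: int = 1000,
    seed: int = 0,
    init_scales: np.ndarray | None = None,
    init_jitter: float = 0.5,
    block_moves: Sequence[BlockMove] = (),
) -> MCMCResult:
    """Sample from ``exp(logpost)`` with adaptive Metropolis-within-Gibbs.

    ``logpost`` must map a (chains, dim) state matrix to (chains,) log
    densities (unnormalized). ``x0`` is either a (dim,) vector — chains
    start there plus jitter scaled by ``init_scales`` — or an explicit
    (chains, dim) matrix of starting states.
    """
    x0 = np.asarray(x0, float)
    dim = x0.shape[-1]
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    rng = np.random.default_rng(seed)
    scales = np.ones(dim) if init_scales is None else np.asarray(init_scales, float)
    if x0.ndim == 2:
        if x0.shape[0] != n_chains:
            raise ValueError("2-D x0 must have n_chains rows")
        X = x0.copy()
    else:
        X = x0[None, :] + init_jitter * scales[None, :] * rng.standard_normal((n_chains, dim))
    log_s = np.log(np.broadcast_to(scales, (n_chains, dim))).copy()
    log_s_block = np.full((n_chains, len(block_moves)), np.log(0.5))
    lp = logpost(X)
    if not np.all(np.isfinite(lp)):
        # fall back to the unjittered start for chains born in a flat region
        X[~np.isfinite(lp)] = x0 if x0.ndim == 1 else x0[~np.isfinite(lp)]
        lp = logpost(X)
    if not np.all(np.isfinite(lp)):
        raise ValueError("log posterior is not finite at the initial state")

    out = np.empty((n_chains, draws, dim))
    acc_count = np.zeros((n_chains, dim))
    for it in range(warmup + draws):
        gamma = min(0.5, (it + 1) ** -0.6)
        for j in range(dim):
            old = X[:, j].copy()
            X[:, j] = old + np.exp(log_s[:, j]) * rng.standard_normal(n_chains)
            lp_new = logpost(X)
            accept = np.log(rng.uniform(size=n_chains)) < (lp_new - lp)
            X[~accept, j] = old[~accept]
            lp = np.where(accept, lp_new, lp)
            if it < warmup:
                log_s[:, j] += gamma * (accept.astype(float) - _TARGET_ACCEPT)
            else:
                acc_count[:, j] += accept
        for b, move in enumerate(block_moves):
            X_prop, log_jac = move(X, np.exp(log_s_block[:, b]), rng)
            lp_new = logpost(X_prop)
            accept = np.log(rng.uniform(size=n_chains)) < (lp_new - lp + log_jac)
            X[accept] = X_prop[accept]
            lp = np.where(accept, lp_new, lp)
            if it < warmup:
                log_s_block[:, b] += gamma * (accept.astype(float) - _TARGET_ACCEPT_BLOCK)
        if it >= warmup:
            out[:, it - warmup, :] = X
    return MCMCResult(samples=out, accept_rate=acc_count / max(draws, 1))


def rhat(chain_draws: np.ndarray) -> float:
    """Split-R-hat of a (chains, draws) array (via arviz)."""
    import arviz as az

    return float(az.rhat(np.asarray(chain_draws)))


def ess(chain_draws: np.ndarray) -> float:
    """Bulk effective sample size of a (chains, draws) array (via arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(chain_draws)))
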