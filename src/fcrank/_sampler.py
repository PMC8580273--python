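"""Adaptive random-walk Metropolis, vectorized across independent chains.

Haario-style adaptation: during warmup the proposal covariance is re-fitted
every 250 iterations to the pooled recent history of all chains and the
global scale is nudged toward a target acceptance rate; both are frozen
before the retained sampling phase so the kept draws come from a valid,
time-homogeneous Markov chain.  Chains share the (vectorized) proposal
stream but never exchange state, so split-Rhat across chains is an honest
convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TARGET_ACCEPT = 0.28
_ADAPT_EVERY = 250


@dataclass
class SamplerRun:
    """Raw output: draws shaped (chains, draws_per_chain, ndim)."""

    draws: np.ndarray
    accept_rate: float


def run_rwm(
    log_posterior,
    x0: np.ndarray,
    *,
    chains: int,
    warmup: int,
    iterations: int,
    thin: int,
    rng: np.random.Generator,
    init_jitter: float = 0.2,
) -> SamplerRun:
    """Sample ``log_posterior`` (vectorized over rows) from ``chains``
    independent walkers started at ``x0`` plus Gaussian jitter."""
    ndim = x0.size
    cur = x0[None, :] + init_jitter * rng.standard_normal((chains, ndim))
    lp_cur = log_posterior(cur)
    # fall back to x0 for any jittered start with -inf posterior
    bad = ~np.isfinite(lp_cur)
    if bad.any():
        cur[bad] = x0
        lp_cur = log_posterior(cur)
    L = np.linalg.cholesky(np.eye(ndim) * 0.01)
    scale = 2.38 / np.sqrt(ndim)
    history: list[np.ndarray] = []
    acc_n = acc_d = 0
    for it in range(warmup):
        prop = cur + scale * (rng.standard_normal((chains, ndim)) @ L.T)
        lp_prop = log_posterior(prop)
        accept = np.log(rng.random(chains)) < lp_prop - lp_cur
        cur[accept] = prop[accept]
        lp_cur[accept] = lp_prop[accept]
        acc_n += int(accept.sum())
        acc_d += chains
        history.append(cur.copy())
        if (it + 1) % _ADAPT_EVERY == 0:
            rate = acc_n / acc_d
            acc_n = acc_d = 0
            scale *= float(np.exp(1.2 * (rate - _TARGET_ACCEPT)))
            recent = np.asarray(history[len(history) // 2 :]).reshape(-1, ndim)
            if recent.shape[0] > 10 * ndim:
                cov = np.cov(recent.T) + 1e-8 * np.eye(ndim)
                L = np.linalg.cholesky(cov)
    keep = iterations // thin
    draws = np.empty((chains, keep, ndim))
    acc = 0
    for it in range(keep * thin):
        prop = cur + scale * (rng.standard_normal((chains, ndim)) @ L.T)
        lp_prop = log_posterior(prop)
        accept = np.log(rng.random(chains)) < lp_prop - lp_cur
        cur[accept] = prop[accept]
        lp_cur[accept] = lp_prop[accept]
        acc += int(accept.sum())
        if (it + 1) % thin == 0:
            draws[:, it // thin, :] = cur
    return SamplerRun(draws=draws, accept_rate=acc / (keep * thin * chains))
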