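"""Shared MCMC machinery: settings, convergence and summaries.

Every sampler in the package follows the same conventions: 4 chains, the
first 2000 iterations discarded as burn-in, the next 4000 retained, and
convergence declared only when the Gelman-Rubin statistic is below 1.1
for all parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RHAT_THRESHOLD = 1.1


@dataclass
class MCMCSettings:
    chains: int = 4
    burn_in: int = 2000
    draws: int = 4000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.burn_in < 0 or self.draws < 1:
            raise ValueError("invalid MCMC settings")

    def rngs(self, salt: int = 0) -> list[np.random.Generator]:
        return [np.random.default_rng((int(self.seed) & 0x7FFFFFFF, salt, c))
                for c in range(self.chains)]


def reduced(settings: MCMCSettings, chains: int = 2, burn_in: int = 500,
            draws: int = 1000) -> MCMCSettings:
    """Smaller settings for replicate studies; same seed stream."""
    return MCMCSettings(chains=chains, burn_in=burn_in, draws=draws,
                        seed=settings.seed)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_iterations).  Each chain is split in
    half, so C chains yield 2C sequences.  Degenerate (zero-variance)
    chains return exactly 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (chain, iteration)")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short for split-Rhat")
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w < 1e-300 and b < 1e-300:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def batch_means_mcse(draws: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the mean by the batch-means method,
    robust to autocorrelation in the chain."""
    x = np.asarray(draws, dtype=float).ravel()
    m = len(x) // n_batches
    if m < 2:
        return float(x.std(ddof=1) / np.sqrt(max(len(x), 2)))
    batches = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def central_interval(draws: np.ndarray, prob: float = 0.95):
    a = (1.0 - prob) / 2.0
    lo, hi = np.quantile(np.asarray(draws).ravel(), [a, 1.0 - a])
    return float(lo), float(hi)


def sample_inverse_gamma(rng: np.random.Generator, shape: float,
                         scale: float) -> float:
    """One draw from InvGamma(shape, scale) (scale = rate of the Gamma)."""
    return float(scale / rng.gamma(shape))


def summarize_draws(draws: np.ndarray) -> dict:
    x = np.asarray(draws, dtype=float)
    flat = x.ravel()
    lo, hi = central_interval(flat)
    out = dict(mean=float(flat.mean()), median=float(np.median(flat)),
               sd=float(flat.std(ddof=1)), lower=lo, upper=hi,
               mcse=batch_means_mcse(flat))
    if x.ndim == 2 and x.shape[0] > 1:
        out["rhat"] = gelman_rubin(x)
    return out
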