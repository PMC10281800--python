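"""Timing variance and repeatability of migratory milestones.

Repeatability R is the proportion of total timing variance attributable to
consistent between-individual differences,
``R = sigma2_between / (sigma2_between + sigma2_within)``, estimated from a
one-way random-intercept (variance-components) normal model with no fixed
effects, individual as the random effect and milestone date as response.
The model is fitted with a conjugate Gibbs sampler.  The default priors on
the between- and within-individual SDs are half-Student-t(3, 0, 2.5*sd(y)),
the convention of the mixed-model software this analysis style comes from,
implemented with the usual inverse-gamma auxiliary-variable scheme; a plain
inverse-gamma(0.001, 0.001) prior on the variances is available by
configuration.  The grand mean has a flat Normal(0, 1000 days) prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import (MCMCSettings, RHAT_THRESHOLD, central_interval,
                   gelman_rubin, sample_inverse_gamma)

IG_SHAPE = 0.001
IG_SCALE = 0.001
MEAN_PRIOR_SD = 1000.0


def milestone_variance(dates, prob: float = 0.95) -> dict:
    """Sample variance of milestone dates with a posterior interval.

    The interval is the analytic posterior of the variance of a normal
    model (flat prior on the mean, inverse-gamma(0.001, 0.001) on the
    variance), consistent with the Bayesian machinery used elsewhere.
    """
    x = np.asarray(dates, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 dates to estimate a variance")
    v = float(x.var(ddof=1))
    sse = v * (n - 1)
    if sse <= 0:
        return dict(variance=0.0, lower=0.0, upper=0.0, n=n, degenerate=True)
    a = IG_SHAPE + (n - 1) / 2.0
    b = IG_SCALE + sse / 2.0
    alpha = (1 - prob) / 2
    lo, hi = stats.invgamma.ppf([alpha, 1 - alpha], a, scale=b)
    return dict(variance=v, lower=float(lo), upper=float(hi), n=n,
                degenerate=False)


def variance_f_test(v1: float, n1: int, v2: float, n2: int) -> tuple[float, float]:
    """Two-sided F-test comparing two sample variances.

    F = v1/v2 on (n1-1, n2-1) df; p = 2*min(P(F<=f), P(F>=f)), capped at 1.
    """
    if min(n1, n2) < 2 or v2 <= 0:
        raise ValueError("need n >= 2 per sample and positive denominator")
    f = v1 / v2
    d1, d2 = n1 - 1, n2 - 1
    p = 2.0 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
    return float(f), float(min(p, 1.0))


@dataclass
class VarianceComponents:
    """Posterior of the one-way random-intercept model."""

    sigma2_between: np.ndarray   # (chains, draws)
    sigma2_within: np.ndarray
    mu: np.ndarray
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    n: int = 0
    n_birds: int = 0

    @property
    def r_draws(self) -> np.ndarray:
        return self.sigma2_between / (self.sigma2_between + self.sigma2_within)

    def summary(self) -> dict:
        r = self.r_draws.ravel()
        r_lo, r_hi = central_interval(r)
        vb, vw = self.sigma2_between.ravel(), self.sigma2_within.ravel()
        return dict(
            R=float(np.median(r)), R_lower=r_lo, R_upper=r_hi,
            sigma2_between=float(np.median(vb)),
            sigma2_within=float(np.median(vw)),
            rhat=dict(self.rhat), converged=self.converged,
            n=self.n, n_birds=self.n_birds)


def fit_variance_components(dates, bird_ids,
                            mcmc: MCMCSettings | None = None,
                            prior: str = "half_t") -> VarianceComponents:
    """Gibbs sampler for dates ~ 1 + (1 | bird).

    Conjugate normal/inverse-gamma updates throughout; ``prior`` selects
    "half_t" (default, half-t(3) on both SDs scaled by 2.5*sd(y)) or
    "invgamma" (inverse-gamma(0.001, 0.001) on both variances).
    Non-convergence (any Rhat >= 1.1) flags the result rather than raising.
    """
    mcmc = mcmc if mcmc is not None else MCMCSettings()
    if prior not in ("half_t", "invgamma"):
        raise ValueError(f"unknown prior family {prior!r}")
    y = np.asarray(dates, dtype=float)
    birds, idx = np.unique(np.asarray(bird_ids), return_inverse=True)
    n, n_birds = len(y), len(birds)
    if n_birds < 2:
        raise ValueError("need at least two individuals")
    counts = np.bincount(idx, minlength=n_birds).astype(float)
    if counts.max() < 2:
        raise ValueError("need at least one individual with repeated records")
    sums_template = np.zeros(n_birds)
    total_var = max(y.var(ddof=1), 1e-8)
    half_t_nu = 3.0
    half_t_scale2 = (2.5 * np.sqrt(total_var)) ** 2

    out_b = np.empty((mcmc.chains, mcmc.draws))
    out_w = np.empty((mcmc.chains, mcmc.draws))
    out_mu = np.empty((mcmc.chains, mcmc.draws))
    for c, rng in enumerate(mcmc.rngs(salt=101)):
        mu = float(y.mean())
        s2b = total_var / 2.0
        s2w = total_var / 2.0
        aux_b = aux_w = 1.0
        b = np.zeros(n_birds)
        for it in range(mcmc.burn_in + mcmc.draws):
            # individual intercepts
            sums = sums_template.copy()
            np.add.at(sums, idx, y - mu)
            prec = counts / s2w + 1.0 / s2b
            mean = (sums / s2w) / prec
            b = mean + rng.standard_normal(n_birds) / np.sqrt(prec)
            # grand mean
            resid = y - b[idx]
            prec_mu = n / s2w + 1.0 / MEAN_PRIOR_SD**2
            mu = float(rng.normal((resid.sum() / s2w) / prec_mu,
                                  1.0 / np.sqrt(prec_mu)))
            # variances
            err = y - mu - b[idx]
            if prior == "half_t":
                s2b = sample_inverse_gamma(
                    rng, (n_birds + half_t_nu) / 2.0,
                    half_t_nu / aux_b + 0.5 * float(b @ b))
                aux_b = sample_inverse_gamma(
                    rng, (half_t_nu + 1) / 2.0,
                    half_t_nu / s2b + 1.0 / half_t_scale2)
                s2w = sample_inverse_gamma(
                    rng, (n + half_t_nu) / 2.0,
                    half_t_nu / aux_w + 0.5 * float(err @ err))
                aux_w = sample_inverse_gamma(
                    rng, (half_t_nu + 1) / 2.0,
                    half_t_nu / s2w + 1.0 / half_t_scale2)
            else:
                s2b = sample_inverse_gamma(rng, IG_SHAPE + n_birds / 2.0,
                                           IG_SCALE + 0.5 * float(b @ b))
                s2w = sample_inverse_gamma(rng, IG_SHAPE + n / 2.0,
                                           IG_SCALE + 0.5 * float(err @ err))
            if it >= mcmc.burn_in:
                j = it - mcmc.burn_in
                out_b[c, j], out_w[c, j], out_mu[c, j] = s2b, s2w, mu
    rhat = {}
    if mcmc.chains > 1:
        rhat = {"sigma2_between": gelman_rubin(np.log(out_b)),
                "sigma2_within": gelman_rubin(np.log(out_w)),
                "mu": gelman_rubin(out_mu)}
    converged = all(v < RHAT_THRESHOLD for v in rhat.values()) if rhat else True
    return VarianceComponents(sigma2_between=out_b, sigma2_within=out_w,
                              mu=out_mu, rhat=rhat, converged=converged,
                              n=n, n_birds=n_birds)


def repeatability_summary(per_milestone: dict) -> dict:
    """Cross-milestone repeatability table with mean and range.

    ``per_milestone`` maps milestone kind to either a VarianceComponents
    fit or a dict with keys R / R_lower / R_upper.
    """
    table = {}
    for kind, vc in per_milestone.items():
        s = vc.summary() if isinstance(vc, VarianceComponents) else dict(vc)
        table[kind] = dict(
            estimate=round(float(s["R"]), 10),
            lower=float(s.get("R_lower", np.nan)),
            upper=float(s.get("R_upper", np.nan)),
            well_supported=bool(s.get("R_lower", 0) > 0.01))
    ests = [v["estimate"] for v in table.values()]
    return dict(milestones=table,
                mean=float(np.mean(ests)),
                min=float(np.min(ests)),
                max=float(np.max(ests)))


def consecutive_variance_tests(milestone_table: pd.DataFrame,
                               kinds: list[str]) -> pd.DataFrame:
    """F-tests between consecutive milestones' date variances (the pairwise
    comparisons displayed alongside the variance profile)."""
    rows = []
    for a, b in zip(kinds[:-1], kinds[1:]):
        xa = milestone_table.loc[milestone_table["kind"] == a,
                                 "date_cycle_days"].dropna()
        xb = milestone_table.loc[milestone_table["kind"] == b,
                                 "date_cycle_days"].dropna()
        if len(xa) < 2 or len(xb) < 2:
            continue
        f, p = variance_f_test(xa.var(ddof=1), len(xa), xb.var(ddof=1), len(xb))
        rows.append(dict(from_kind=a, to_kind=b, F=f, p=p,
                         n1=len(xa), n2=len(xb)))
    return pd.DataFrame(rows)
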