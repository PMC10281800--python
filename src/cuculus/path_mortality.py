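"""Timing -> mortality path models.

For each milestone (except departure from the wintering grounds, where
mortality events in the following stage are too scarce), mortality in the
next migration stage is a binary outcome modelled by Bayesian logistic
regression on standardized milestone timing, with breeding-habitat and
route main effects and a habitat x timing interaction; a simultaneous
linear sub-model of timing on habitat and route completes the two-equation
path structure.  A combined analysis pools the three milestones following
the stages that most positively impact breeding-grounds arrival (southbound
Sahara crossing, West-Africa departure, breeding arrival) with
milestone-specific intercepts and a shared timing slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .dag import MILESTONES
from .mcmc import (MCMCSettings, RHAT_THRESHOLD, central_interval,
                   gelman_rubin, sample_inverse_gamma)

COEF_PRIOR_SD = 5.0
EXCLUDED_KIND = "depart_winter"
COMBINED_KINDS = ("complete_sahara_south", "depart_west_africa",
                  "arrive_breeding")


def build_mortality_dataset(milestones: pd.DataFrame, deaths: pd.DataFrame,
                            meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-milestone mortality records.

    One record per (cycle, milestone): standardized-later timing, habitat,
    route, and a 0/1 indicator of death in the stage following that
    milestone.  Uncertain mortality events (certainty flag false) are
    dropped; departure from the wintering grounds is excluded.
    """
    death_map = {}
    uncertain = set()
    if len(deaths):
        for _, d in deaths.iterrows():
            if bool(d.get("certain", True)):
                death_map[d["cycle_id"]] = d["death_after"]
            else:
                uncertain.add(d["cycle_id"])
    meta_idx = meta.set_index("bird_id")
    out: dict[str, pd.DataFrame] = {}
    for kind in MILESTONES:
        if kind == EXCLUDED_KIND:
            continue
        sub = milestones[milestones["kind"] == kind]
        rows = []
        for _, m in sub.iterrows():
            if m["cycle_id"] in uncertain:
                continue
            if m["bird_id"] not in meta_idx.index:
                continue
            rows.append(dict(
                bird_id=m["bird_id"], cycle_id=m["cycle_id"], kind=kind,
                timing=float(m["date_cycle_days"]),
                habitat=meta_idx.loc[m["bird_id"], "habitat"],
                route=meta_idx.loc[m["bird_id"], "route"],
                died_next_stage=int(death_map.get(m["cycle_id"]) == kind)))
        df = pd.DataFrame(rows, columns=["bird_id", "cycle_id", "kind",
                                         "timing", "habitat", "route",
                                         "died_next_stage"])
        if len(df) >= 2 and df["timing"].std(ddof=1) > 0:
            df["timing"] = (df["timing"] - df["timing"].mean()) / df["timing"].std(ddof=1)
        out[kind] = df
    return out


@dataclass
class MortalityFit:
    """Posterior of the two-equation timing/mortality path model."""

    names: list[str]
    coef: np.ndarray                      # (chains, draws, p) logistic part
    timing_model: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    prior_dominated: bool = False
    n: int = 0
    n_deaths: int = 0

    def draws(self, name: str) -> np.ndarray:
        return self.coef[:, :, self.names.index(name)]

    def p_nonzero(self, name: str) -> float:
        x = self.draws(name).ravel()
        pos = float(np.mean(x > 0))
        return max(pos, 1.0 - pos)

    def summary(self) -> dict:
        rows = {}
        for i, nm in enumerate(self.names):
            d = self.coef[:, :, i].ravel()
            lo, hi = central_interval(d)
            rows[nm] = dict(mean=float(d.mean()), median=float(np.median(d)),
                            lower=lo, upper=hi, p_nonzero=self.p_nonzero(nm))
        # within-stratum timing effects (habitat coded upland=1)
        if "timing" in self.names and "habitat_x_timing" in self.names:
            low = self.draws("timing").ravel()
            up = low + self.draws("habitat_x_timing").ravel()
            for nm, d in (("timing_lowland", low), ("timing_upland", up)):
                lo, hi = central_interval(d)
                pos = float(np.mean(d > 0))
                rows[nm] = dict(mean=float(d.mean()), median=float(np.median(d)),
                                lower=lo, upper=hi,
                                p_nonzero=max(pos, 1.0 - pos))
        return dict(coefficients=rows, timing_model=self.timing_model,
                    rhat=self.rhat, converged=self.converged,
                    prior_dominated=self.prior_dominated,
                    n=self.n, n_deaths=self.n_deaths)


def _logistic_mh(X: np.ndarray, y: np.ndarray, mcmc: MCMCSettings,
                 salt: int, prior_sd: float = COEF_PRIOR_SD):
    """Metropolis sampler for Bayesian logistic regression.

    The proposal is a scaled Laplace approximation (MAP + inverse Hessian),
    which mixes well at these small n; separation is kept in check by the
    Normal(0, prior_sd²) prior.
    """
    n, p = X.shape
    prior_prec = 1.0 / prior_sd**2

    def neg_log_post(b):
        eta = X @ b
        return (np.sum(np.logaddexp(0.0, eta)) - y @ eta
                + 0.5 * prior_prec * b @ b)

    def grad(b):
        mu = special.expit(X @ b)
        return X.T @ (mu - y) + prior_prec * b

    res = optimize.minimize(neg_log_post, np.zeros(p), jac=grad, method="BFGS")
    bmap = res.x
    mu = special.expit(X @ bmap)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    hess = X.T @ (X * w[:, None]) + prior_prec * np.eye(p)
    cov = np.linalg.inv(hess)
    chol = np.linalg.cholesky(cov) * (2.4 / np.sqrt(p))
    out = np.empty((mcmc.chains, mcmc.draws, p))
    accept = 0
    total = 0
    for c, rng in enumerate(mcmc.rngs(salt=salt)):
        b = bmap + 0.1 * chol @ rng.standard_normal(p)
        lp = -neg_log_post(b)
        for it in range(mcmc.burn_in + mcmc.draws):
            prop = b + chol @ rng.standard_normal(p)
            lp_prop = -neg_log_post(prop)
            total += 1
            if np.log(rng.random()) < lp_prop - lp:
                b, lp = prop, lp_prop
                accept += 1
            if it >= mcmc.burn_in:
                out[c, it - mcmc.burn_in] = b
    return out, accept / max(total, 1)


def _timing_submodel(records: pd.DataFrame, mcmc: MCMCSettings,
                     salt: int) -> dict:
    """Conjugate Bayesian linear model: timing ~ habitat + route."""
    hab = (records["habitat"] == "upland").astype(float).to_numpy()
    rt = (records["route"] == "SE").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(records)), hab, rt])
    y = records["timing"].to_numpy(dtype=float)
    names = ["intercept", "habitat", "route"]
    prior_prec = np.eye(3) / COEF_PRIOR_SD**2
    draws = np.empty((mcmc.chains, mcmc.draws, 3))
    for c, rng in enumerate(mcmc.rngs(salt=salt + 1)):
        s2 = 1.0
        for it in range(mcmc.burn_in + mcmc.draws):
            prec = X.T @ X / s2 + prior_prec
            mean = np.linalg.solve(prec, X.T @ y / s2)
            L = np.linalg.cholesky(prec)
            b = mean + np.linalg.solve(L.T, rng.standard_normal(3))
            r = y - X @ b
            s2 = sample_inverse_gamma(rng, 0.001 + len(y) / 2.0,
                                      0.001 + 0.5 * float(r @ r))
            if it >= mcmc.burn_in:
                draws[c, it - mcmc.burn_in] = b
        del s2
    out = {}
    for i, nm in enumerate(names):
        d = draws[:, :, i].ravel()
        lo, hi = central_interval(d)
        pos = float(np.mean(d > 0))
        out[nm] = dict(mean=float(d.mean()), lower=lo, upper=hi,
                       p_nonzero=max(pos, 1.0 - pos))
    return out


def fit_mortality_model(records: pd.DataFrame,
                        mcmc: MCMCSettings | None = None,
                        interaction: bool = True) -> MortalityFit:
    """Two-equation mortality path model for one milestone.

    An all-survivor (or all-death) outcome yields a prior-dominated fit
    flagged on the result rather than an error.
    """
    mcmc = mcmc if mcmc is not None else MCMCSettings()
    y = records["died_next_stage"].to_numpy(dtype=float)
    t = records["timing"].to_numpy(dtype=float)
    hab = (records["habitat"] == "upland").astype(float).to_numpy()
    rt = (records["route"] == "SE").astype(float).to_numpy()
    cols = [np.ones(len(records)), t, hab, rt]
    names = ["intercept", "timing", "habitat", "route"]
    if interaction:
        cols.append(hab * t)
        names.append("habitat_x_timing")
    X = np.column_stack(cols)
    draws, _ = _logistic_mh(X, y, mcmc, salt=303)
    rhat = {}
    if mcmc.chains > 1:
        rhat = {nm: gelman_rubin(draws[:, :, i]) for i, nm in enumerate(names)}
    return MortalityFit(
        names=names, coef=draws,
        timing_model=_timing_submodel(records, mcmc, salt=303),
        rhat=rhat,
        converged=all(v < RHAT_THRESHOLD for v in rhat.values()) if rhat else True,
        prior_dominated=bool(y.min() == y.max()),
        n=len(y), n_deaths=int(y.sum()))


def combined_milestones_fit(per_kind: dict[str, pd.DataFrame],
                            kinds=COMBINED_KINDS,
                            mcmc: MCMCSettings | None = None) -> MortalityFit:
    """Pooled fit over the given milestones: milestone-specific intercepts,
    one shared slope on within-milestone-standardized timing."""
    mcmc = mcmc if mcmc is not None else MCMCSettings()
    frames = []
    for kind in kinds:
        df = per_kind.get(kind)
        if df is None or len(df) == 0:
            continue
        d = df.copy()
        sd = d["timing"].std(ddof=1)
        if np.isfinite(sd) and sd > 0:
            d["timing"] = (d["timing"] - d["timing"].mean()) / sd
        frames.append(d)
    if not frames:
        raise ValueError("no records for any of the pooled milestones")
    pooled = pd.concat(frames, ignore_index=True)
    present = [k for k in kinds if (pooled["kind"] == k).any()]
    dummies = np.column_stack([(pooled["kind"] == k).to_numpy(float)
                               for k in present])
    X = np.column_stack([dummies, pooled["timing"].to_numpy(float)])
    names = [f"intercept[{k}]" for k in present] + ["timing"]
    y = pooled["died_next_stage"].to_numpy(float)
    draws, _ = _logistic_mh(X, y, mcmc, salt=404)
    rhat = {}
    if mcmc.chains > 1:
        rhat = {nm: gelman_rubin(draws[:, :, i]) for i, nm in enumerate(names)}
    return MortalityFit(
        names=names, coef=draws, timing_model={}, rhat=rhat,
        converged=all(v < RHAT_THRESHOLD for v in rhat.values()) if rhat else True,
        prior_dominated=bool(y.min() == y.max()),
        n=len(y), n_deaths=int(y.sum()))
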