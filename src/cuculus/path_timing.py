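"""Bayesian path analysis of migration timing over a declared DAG.

A piecewise structural equation model on observed variables only: each
endogenous milestone is a linear-normal function of its DAG parents, all
variables z-scored, so coefficients are standardized path coefficients,
their squares are variance shares, and indirect effects are products of
coefficients along a path.  The system is fitted jointly by Gibbs
sampling; missing entries (in predictors or responses) are sampled from
their full conditionals each sweep, propagating imputation uncertainty
into the coefficient posteriors.  Directed-separation tests (Fisher's C)
check the conditional independences the DAG implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dag import DagSpec
from .mcmc import (MCMCSettings, RHAT_THRESHOLD, central_interval,
                   gelman_rubin, sample_inverse_gamma)

COEF_PRIOR_SD = 10.0
IG_SHAPE = 0.001
IG_SCALE = 0.001
SUPPORT_TIERS = ((0.95, "very well-supported"), (0.90, "well-supported"),
                 (0.80, "likely"))


def standardize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """z-score the named columns (mean 0, SD 1 over non-missing entries,
    population SD).  Binary covariates are coded 0/1 upstream and
    standardized identically so the squaring rule defines their variance
    shares.  Standardized path coefficients are invariant to the ddof
    convention (both variables rescale by the same factor)."""
    out = table.copy()
    for c in columns:
        x = out[c].astype(float)
        sd = x.std(ddof=0, skipna=True)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (x - x.mean(skipna=True)) / sd
    return out


def encode_binary(table: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Code categorical covariates 0/1 (e.g. habitat upland=1, route SE=1)."""
    out = table.copy()
    for col, one_level in mapping.items():
        out[col] = (out[col] == one_level).astype(float)
    return out


@dataclass
class PathFit:
    """Posterior of all standardized path coefficients for a declared DAG."""

    dag: DagSpec
    edges: list[tuple[str, str]]
    coef: dict = field(default_factory=dict)        # edge -> (chains, draws)
    resid_var: dict = field(default_factory=dict)   # node -> (chains, draws)
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    n: int = 0

    def edge_draws(self, a: str, b: str) -> np.ndarray:
        return self.coef[(a, b)]

    def edge_probability(self, a: str, b: str) -> float:
        return edge_probability(self.coef[(a, b)])

    def edge_r2(self, a: str, b: str) -> dict:
        return variance_explained(self.coef[(a, b)])

    def node_r2(self, node: str) -> float:
        """Model R² of one node equation (1 - residual variance on the
        standardized scale), posterior median."""
        return float(1.0 - np.median(self.resid_var[node]))

    def summary_table(self, threshold: float = 0.0) -> pd.DataFrame:
        return summarize_paths(self, headline_threshold=threshold)


def edge_probability(draws: np.ndarray) -> float:
    """Probability that a path coefficient is non-zero in the sampled
    direction: max of the posterior mass above and below zero."""
    x = np.asarray(draws).ravel()
    pos = float(np.mean(x > 0))
    return max(pos, 1.0 - pos)


def variance_explained(coef) -> dict:
    """Variance share of a direct path: the squared standardized
    coefficient, in percent.  Accepts a scalar or posterior draws."""
    x = np.asarray(coef, dtype=float)
    if x.ndim == 0:
        pct = float(100.0 * x**2)
        return dict(pct=round(pct, 1), pct_raw=pct)
    sq = 100.0 * x.ravel() ** 2
    lo, hi = central_interval(sq)
    med = float(np.median(sq))
    return dict(pct=round(med, 1), pct_raw=med, lower=lo, upper=hi)


def indirect_effect(*edge_draws) -> dict:
    """Indirect effect along an ordered multi-edge path: the draw-wise
    product of the step coefficients."""
    arrs = [np.asarray(d, dtype=float).ravel() for d in edge_draws]
    m = min(len(a) for a in arrs)
    prod = np.ones(m)
    for a in arrs:
        prod = prod * a[:m]
    lo, hi = central_interval(prod) if m > 1 else (float(prod[0]), float(prod[0]))
    return dict(effect=float(np.median(prod)), lower=lo, upper=hi,
                probability=edge_probability(prod))


def chain_variance_share(stage_shares) -> float:
    """Variance share of a chained path, as a percentage of the terminal
    node's variance: the product of the stage shares (each a fraction)."""
    shares = np.asarray(stage_shares, dtype=float)
    return round(float(100.0 * np.prod(shares)), 1)


def residual_share(direct_shares_pct) -> float:
    """Unexplained percentage reported alongside a printed decomposition:
    100 minus the sum of the printed direct shares."""
    return round(float(100.0 - np.sum(np.asarray(direct_shares_pct, float))), 1)


def fit_path_model(data: pd.DataFrame, dag: DagSpec,
                   mcmc: MCMCSettings | None = None) -> PathFit:
    """Joint Gibbs sampler for the system of node equations.

    ``data`` holds one standardized column per DAG node; missingness is
    allowed anywhere.  Priors: Normal(0, 10²) on coefficients and
    intercepts, inverse-gamma(0.001, 0.001) on residual variances.
    Missing entries are drawn from their full conditionals: the node's own
    equation (or a unit-normal / Bernoulli prior for exogenous variables)
    combined with the equations of every child the variable feeds.
    """
    mcmc = mcmc if mcmc is not None else MCMCSettings()
    dag.validate()
    nodes = dag.all_nodes()
    missing_cols = [c for c in nodes if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks DAG node column(s): {missing_cols}")
    x0 = data[nodes].to_numpy(dtype=float)
    n, p = x0.shape
    node_idx = {v: i for i, v in enumerate(nodes)}
    parents = {v: dag.parents(v) for v in dag.endogenous}
    for v in dag.endogenous:
        n_obs = int(np.sum(~np.isnan(x0[:, node_idx[v]])))
        if n_obs < len(parents[v]) + 2:
            raise ValueError(f"node {v!r} is not identifiable: "
                             f"{n_obs} observations for {len(parents[v])} parents")
    miss_mask = np.isnan(x0)
    edges = sorted(dag.edges, key=lambda e: (nodes.index(e[1]), nodes.index(e[0])))
    children = {v: [(c, dag.parents(c).index(v)) for c in dag.children(v)]
                for v in nodes}
    binary_info = {}
    for v, exo in dag.exogenous.items():
        if exo.kind == "binary":
            col = x0[:, node_idx[v]]
            vals = np.unique(col[~np.isnan(col)])
            if len(vals) >= 2:
                phat = float(np.mean(np.isclose(col[~np.isnan(col)], vals.max())))
                binary_info[v] = (float(vals.min()), float(vals.max()), phat)

    out_coef = {e: np.empty((mcmc.chains, mcmc.draws)) for e in edges}
    out_var = {v: np.empty((mcmc.chains, mcmc.draws)) for v in dag.endogenous}
    prior_prec = 1.0 / COEF_PRIOR_SD**2

    for c_i, rng in enumerate(mcmc.rngs(salt=202)):
        x = x0.copy()
        x[miss_mask] = 0.0
        beta = {v: np.zeros(len(parents[v]) + 1) for v in dag.endogenous}
        s2 = {v: 1.0 for v in dag.endogenous}
        for it in range(mcmc.burn_in + mcmc.draws):
            for v in dag.endogenous:
                pj = [node_idx[q] for q in parents[v]]
                X = np.column_stack([np.ones(n), x[:, pj]])
                y = x[:, node_idx[v]]
                prec = X.T @ X / s2[v] + prior_prec * np.eye(X.shape[1])
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, X.T @ y / s2[v])
                z = rng.standard_normal(X.shape[1])
                beta[v] = mean + np.linalg.solve(L.T, z)
                resid = y - X @ beta[v]
                s2[v] = sample_inverse_gamma(
                    rng, IG_SHAPE + n / 2.0, IG_SCALE + 0.5 * float(resid @ resid))
            _impute(x, miss_mask, dag, nodes, node_idx, parents, children,
                    beta, s2, binary_info, rng)
            if it >= mcmc.burn_in:
                j = it - mcmc.burn_in
                for v in dag.endogenous:
                    out_var[v][c_i, j] = s2[v]
                    for k, q in enumerate(parents[v]):
                        out_coef[(q, v)][c_i, j] = beta[v][k + 1]

    rhat = {}
    if mcmc.chains > 1:
        rhat = {f"{a}->{b}": gelman_rubin(out_coef[(a, b)]) for a, b in edges}
    converged = all(v < RHAT_THRESHOLD for v in rhat.values()) if rhat else True
    return PathFit(dag=dag, edges=edges, coef=out_coef, resid_var=out_var,
                   rhat=rhat, converged=converged, n=n)


def _impute(x, miss_mask, dag, nodes, node_idx, parents, children, beta, s2,
            binary_info, rng):
    for v in nodes:
        j = node_idx[v]
        rows = np.flatnonzero(miss_mask[:, j])
        if len(rows) == 0:
            continue
        if v in binary_info:
            lo, hi, phat = binary_info[v]
            ll_lo = np.full(len(rows), np.log(max(1 - phat, 1e-12)))
            ll_hi = np.full(len(rows), np.log(max(phat, 1e-12)))
            for child, k in children[v]:
                cb = beta[child]
                pj = [node_idx[q] for q in parents[child]]
                base = cb[0] + x[np.ix_(rows, pj)] @ cb[1:]
                partial = base - cb[k + 1] * x[rows, j]
                yc = x[rows, node_idx[child]]
                for val, ll in ((lo, ll_lo), (hi, ll_hi)):
                    mu = partial + cb[k + 1] * val
                    ll += -0.5 * (yc - mu) ** 2 / s2[child]
            pr = 1.0 / (1.0 + np.exp(ll_lo - ll_hi))
            x[rows, j] = np.where(rng.random(len(rows)) < pr, hi, lo)
            continue
        if v in dag.endogenous:
            vb = beta[v]
            pj = [node_idx[q] for q in parents[v]]
            mean0 = vb[0] + x[np.ix_(rows, pj)] @ vb[1:]
            prec0 = np.full(len(rows), 1.0 / s2[v])
        else:
            mean0 = np.zeros(len(rows))
            prec0 = np.ones(len(rows))  # standardized exogenous ~ N(0,1)
        num = prec0 * mean0
        prec = prec0.copy()
        for child, k in children[v]:
            cb = beta[child]
            pj = [node_idx[q] for q in parents[child]]
            base = cb[0] + x[np.ix_(rows, pj)] @ cb[1:]
            partial = base - cb[k + 1] * x[rows, j]
            yc = x[rows, node_idx[child]]
            w = cb[k + 1]
            num += w * (yc - partial) / s2[child]
            prec += w * w / s2[child]
        x[rows, j] = num / prec + rng.standard_normal(len(rows)) / np.sqrt(prec)


def support_tier(p: float) -> str:
    for thr, name in SUPPORT_TIERS:
        if p >= thr:
            return name
    return "unsupported"


def summarize_paths(fit: PathFit, headline_threshold: float = 0.80,
                    thresholds=(0.80, 0.90, 0.95)) -> pd.DataFrame:
    """Edge-level report: coefficient median and interval, probability of
    being non-zero, support tier, variance share.  Edges below the
    headline threshold are flagged rather than removed, so the full table
    remains available."""
    rows = []
    for (a, b) in fit.edges:
        d = fit.coef[(a, b)].ravel()
        lo, hi = central_interval(d)
        prob = edge_probability(d)
        rows.append(dict(
            path=f"{a} -> {b}", source=a, target=b,
            coefficient=float(np.median(d)), lower=lo, upper=hi,
            probability=prob, tier=support_tier(prob),
            r2_pct=variance_explained(d)["pct"],
            headline=prob >= headline_threshold))
    return pd.DataFrame(rows).sort_values(["target", "probability"],
                                          ascending=[True, False]).reset_index(drop=True)


def dsep_basis_set(dag: DagSpec) -> list[tuple[str, str, tuple]]:
    """Shipley basis set: each non-adjacent ordered pair, conditioned on
    the union of both vertices' parents; pairs of exogenous variables are
    skipped (their covariance is unconstrained)."""
    order = list(dag.exogenous) + dag.topological_endogenous()
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if a in dag.exogenous and b in dag.exogenous:
                continue
            if (a, b) in dag.edges or (b, a) in dag.edges:
                continue
            cond = tuple(sorted(set(dag.parents(a)) | set(dag.parents(b))
                                - {a, b}, key=pos.__getitem__))
            claims.append((a, b, cond))
    return claims


def dsep_test(dag: DagSpec, data: pd.DataFrame) -> dict:
    """Directed-separation test of the DAG against the data.

    Each independence claim is tested by the p-value of the partial
    coefficient in a normal linear fit (complete-case rows); Fisher's
    C = -2 sum(ln p) on 2k df gives the global goodness-of-fit p.
    """
    claims = dsep_basis_set(dag)
    rows = []
    logs = []
    for a, b, cond in claims:
        cols = [b, a, *cond]
        sub = data[cols].dropna()
        X = sm.add_constant(sub[[a, *cond]].to_numpy())
        res = sm.OLS(sub[b].to_numpy(), X).fit()
        pval = float(res.pvalues[1])
        rows.append(dict(independent=a, dependent=b,
                         conditioning="+".join(cond), p=pval, n=len(sub)))
        logs.append(np.log(max(pval, 1e-300)))
    c_stat = -2.0 * float(np.sum(logs))
    df = 2 * len(claims)
    p = float(stats.chi2.sf(c_stat, df)) if df > 0 else 1.0
    return dict(claims=pd.DataFrame(rows), C=c_stat if df > 0 else 0.0,
                df=df, p=p)


def anomaly_path_data(anomalies: pd.DataFrame, meta: pd.DataFrame,
                      dag: DagSpec) -> pd.DataFrame:
    """Wide within-individual anomaly table with covariates, ready for the
    anomaly variant of the timing model (same structure, anomaly response)."""
    wide = anomalies.pivot_table(index=["bird_id", "cycle_id"],
                                 columns="kind", values="anomaly_days",
                                 aggfunc="first").reset_index()
    wide.columns.name = None
    for m in dag.endogenous:
        if m not in wide.columns:
            wide[m] = np.nan
    return wide.merge(meta, on="bird_id", how="left")
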