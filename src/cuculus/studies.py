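"""Reference studies: the worked variance-decomposition arithmetic and the
simulation studies that validate each stage of the pipeline.

These functions define the package's validation surface: every quantity
they return is computed at call time by running the pipeline on synthetic
data (or, for the worked arithmetic, by pushing the published standardized
coefficient table through the package's R²/indirect-effect calculus).
Problem sizes are chosen to finish on a single CPU in minutes; see
docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dag import MILESTONES, calibrate_between_fraction, default_timing_dag
from .io import read_regions
from .mcmc import MCMCSettings, batch_means_mcse
from .milestones import extract_milestones
from .path_mortality import combined_milestones_fit, fit_mortality_model
from .path_timing import (chain_variance_share, dsep_test, encode_binary,
                          fit_path_model, residual_share, standardize,
                          variance_explained)
from .repeatability import fit_variance_components, repeatability_summary
from .segmentation import segment
from .synthetic import (SimConfig, apply_missingness, metadata_table,
                        noise_free, render_population, simulate_schedules,
                        truth_milestone_table)

#: Published standardized-coefficient table for the timing model (absolute
#: dates): the direct effects on breeding-grounds arrival and the stage
#: variance shares along the carry-over chain.  These are inputs to the
#: worked arithmetic, not outputs of any fit here.
PUBLISHED = dict(
    coef_wa_departure_to_arrival=0.883,
    coef_winter_departure_to_arrival=-0.329,
    share_crossing_on_wa_departure=0.266,
    share_breeding_departure_on_crossing=0.158,
    share_eu_stopover_on_crossing=0.050,
    share_wa_stopover_on_wa_departure=0.075,
    anomaly_share_winter_departure=11.6,
    anomaly_share_breeding_departure=3.7,
    repeatability_table={
        "depart_breeding": 0.41, "complete_sahara_south": 0.25,
        "arrive_winter": 0.51, "depart_winter": 0.17,
        "depart_west_africa": 0.40, "arrive_breeding": 0.34},
)

#: Repeat-count histogram of the study's repeat dataset: 21 birds with two
#: annual cycles, 6 with three, 3 with five and 1 with six, plus 56
#: single-cycle birds -- 137 cycles from 87 birds.
STUDY_SCALE_YEARS = [2] * 21 + [3] * 6 + [5] * 3 + [6] * 1 + [1] * 56


def worked_decomposition() -> dict:
    """Variance-decomposition arithmetic from the published coefficients.

    Every value is produced by the package's calculus: squaring a
    standardized coefficient for a direct share, multiplying stage shares
    along a chain for an indirect share, and closing a printed
    decomposition by subtraction for the unexplained remainder.
    """
    p = PUBLISHED
    direct_wa = variance_explained(p["coef_wa_departure_to_arrival"])
    direct_winter = variance_explained(p["coef_winter_departure_to_arrival"])
    wa_share = direct_wa["pct_raw"] / 100.0
    rep = repeatability_summary(
        {k: dict(R=v, R_lower=np.nan, R_upper=np.nan)
         for k, v in p["repeatability_table"].items()})
    return {
        "arrival_variance_from_wa_departure_pct": direct_wa["pct"],
        "arrival_variance_from_winter_departure_pct": direct_winter["pct"],
        "arrival_variance_via_breeding_departure_chain_pct":
            chain_variance_share([p["share_breeding_departure_on_crossing"],
                                  p["share_crossing_on_wa_departure"],
                                  wa_share]),
        "arrival_variance_from_wa_stopover_lon_pct":
            chain_variance_share([p["share_wa_stopover_on_wa_departure"],
                                  wa_share]),
        "arrival_variance_from_eu_stopover_lat_pct":
            chain_variance_share([p["share_eu_stopover_on_crossing"],
                                  p["share_crossing_on_wa_departure"],
                                  wa_share]),
        "arrival_unexplained_pct":
            residual_share([direct_wa["pct"], direct_winter["pct"]]),
        "anomaly_final_step_share_with_breeding_departure_pct":
            residual_share([p["anomaly_share_winter_departure"],
                            p["anomaly_share_breeding_departure"]]),
        "anomaly_final_step_share_pct":
            residual_share([p["anomaly_share_winter_departure"]]),
        "mean_repeatability": round(rep["mean"], 2),
        "repeatability_range_min": rep["min"],
        "repeatability_range_max": rep["max"],
    }


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------

def _study_scale_records(seed: int, dag):
    cfg = SimConfig(n_birds=87, n_years=6, seed=seed,
                    mortality_enabled=False, dag=dag)
    recs = simulate_schedules(cfg)
    return [r for r in recs
            if r.year < STUDY_SCALE_YEARS[int(r.bird_id[2:])]]


def _standardized(truth: pd.DataFrame, dag) -> pd.DataFrame:
    data = encode_binary(truth, {"habitat": "upland", "route": "SE"})
    cols = [c for c in dag.all_nodes()
            if data[c].dropna().nunique() >= 2]
    return standardize(data, cols)


def oracle_equivalence_study(seed: int = 1) -> dict:
    """Complete-data equivalence of the Bayesian machinery with its
    frequentist oracles at n = 2000.

    Path model: every edge's posterior mean versus node-wise least squares,
    in Monte-Carlo-SE units.  Variance components: posterior means of both
    variances versus the one-way ANOVA (method-of-moments) estimates, in
    percent.
    """
    dag = default_timing_dag()
    cfg = SimConfig(n_birds=1000, n_years=2, seed=seed,
                    mortality_enabled=False)
    data = _standardized(truth_milestone_table(simulate_schedules(cfg)),
                         dag)[dag.all_nodes()]
    mc = MCMCSettings(chains=2, burn_in=500, draws=1500, seed=seed)
    fit = fit_path_model(data, dag, mc)
    worst = 0.0
    for v in dag.endogenous:
        pars = dag.parents(v)
        res = sm.OLS(data[v].to_numpy(),
                     sm.add_constant(data[pars].to_numpy())).fit()
        for i, p in enumerate(pars):
            draws = fit.coef[(p, v)]
            mcse = np.sqrt(np.mean([batch_means_mcse(c) ** 2
                                    for c in draws]) / draws.shape[0])
            dev = abs(draws.mean() - res.params[i + 1]) / max(mcse, 1e-12)
            worst = max(worst, dev)

    # variance components vs ANOVA method of moments (balanced 500 x 4)
    rng = np.random.default_rng(seed + 1)
    n_birds, n_years = 500, 4
    b = rng.normal(0, 10, n_birds)
    y = (150 + b[:, None] + rng.normal(0, 12, (n_birds, n_years)))
    ids = np.repeat(np.arange(n_birds), n_years)
    yy = y.ravel()
    vc = fit_variance_components(yy, ids, mc)
    msb = n_years * y.mean(axis=1).var(ddof=1)
    msw = y.var(axis=1, ddof=1).mean()
    mom_w = msw
    mom_b = (msb - msw) / n_years
    post_b = float(vc.sigma2_between.mean())
    post_w = float(vc.sigma2_within.mean())
    return dict(
        path_max_dev_mcse_units=float(worst),
        vc_between_rel_dev_pct=100 * abs(post_b - mom_b) / mom_b,
        vc_within_rel_dev_pct=100 * abs(post_w - mom_w) / mom_w,
        n=len(data))


def parameter_recovery_study(seed: int = 1, n_reps: int = 100,
                             target_r: float = 0.4) -> dict:
    """Frequentist recovery at the study scale (87 birds, 137 cycles,
    10-30% milestone missingness): coverage of 95% intervals over true
    standardized edge coefficients, and median absolute error of the
    posterior-median repeatability for a milestone whose true marginal
    repeatability is ``target_r``."""
    dag = default_timing_dag()
    calibrate_between_fraction(dag, "arrive_winter", target_r)
    mc_path = MCMCSettings(chains=2, burn_in=400, draws=800, seed=seed)
    mc_vc = MCMCSettings(chains=2, burn_in=500, draws=1500, seed=seed)
    covered = total = 0
    r_errors = []
    for rep in range(n_reps):
        rep_seed = (seed * 100_003 + rep) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        recs = _study_scale_records(rep_seed, dag)
        truth = apply_missingness(truth_milestone_table(recs),
                                  rng.uniform(0.10, 0.30), rng)
        data = _standardized(truth, dag)
        for c in dag.all_nodes():
            if c not in data.columns:
                data[c] = np.nan
        fit = fit_path_model(data[dag.all_nodes()], dag, mc_path)
        for e, true_val in dag.edges.items():
            lo, hi = np.quantile(fit.coef[e].ravel(), [0.025, 0.975])
            covered += lo <= true_val <= hi
            total += 1
        sub = truth.dropna(subset=["arrive_winter"])
        vc = fit_variance_components(sub["arrive_winter"].to_numpy(),
                                     sub["bird_id"].to_numpy(), mc_vc)
        r_errors.append(abs(vc.summary()["R"] - target_r))
    return dict(edge_coverage_pct=100.0 * covered / total,
                repeatability_mae=float(np.median(r_errors)),
                n_reps=n_reps, n_edges=len(dag.edges))


def segmentation_fidelity_study(seed: int = 1, n_birds: int = 12,
                                n_years: int = 3) -> dict:
    """Noise-free duty-cycled tracks: worst milestone-recovery error (h),
    recovery fraction, and the stopover boundary cases (49.9 vs 50.1 km,
    20 vs 25 h)."""
    cfg = noise_free(SimConfig(n_birds=n_birds, n_years=n_years, seed=seed,
                               mortality_enabled=False))
    recs = simulate_schedules(cfg)
    fixes = render_population(recs, cfg)
    _, _, stops = segment(fixes)
    regions = read_regions()
    mil = extract_milestones(stops, fixes, regions, metadata_table(recs))
    truth = {(r.bird_id, cfg.start_year + r.year): r for r in recs}
    worst_h = 0.0
    for _, row in mil.iterrows():
        rec = truth[(row["bird_id"], int(row["cycle_id"].split("-")[1]))]
        err = abs(row["date_cycle_days"] - rec.dates[row["kind"]]) * 24
        worst_h = max(worst_h, err)
    recovered_pct = 100.0 * len(mil) / (len(recs) * 6)

    from .geometry import destination_offset_km
    from .segmentation import assign_cycles, best_fix_table, detect_stopovers

    def boundary(km, hours):
        t0 = pd.Timestamp("2015-06-01T00:00:00Z")
        la, lo = destination_offset_km(50.0, 0.0, km, 0.0)
        fx = pd.DataFrame(dict(
            bird_id=["B", "B"], t=[t0, t0 + pd.Timedelta(hours=hours)],
            lat=[50.0, la], lon=[0.0, lo], lc=["3", "3"]))
        return len(detect_stopovers(best_fix_table(assign_cycles(fx))))

    boundary_ok = (boundary(49.9, 58) == 1 and boundary(50.1, 58) == 0
                   and boundary(0.0, 20) == 0 and boundary(0.0, 25) == 1)
    return dict(worst_milestone_error_h=float(worst_h),
                milestones_recovered_pct=float(recovered_pct),
                boundary_cases_correct=int(boundary_ok))


def dsep_calibration_study(seed: int = 1, n_sims: int = 100,
                           n_power: int = 25) -> dict:
    """Fisher's C calibration under the true DAG (one cycle per bird, the
    regime where the claims' independence assumptions hold) and power to
    detect an omitted crossing -> West-Africa-departure edge at n = 137."""
    dag = default_timing_dag()
    ps = []
    for s in range(n_sims):
        cfg = SimConfig(n_birds=137, n_years=1,
                        seed=(seed * 7919 + s) % (2**31 - 1),
                        mortality_enabled=False)
        data = _standardized(truth_milestone_table(simulate_schedules(cfg)),
                             dag)
        ps.append(dsep_test(dag, data)["p"])
    ks_p = float(stats.kstest(ps, "uniform").pvalue)

    reduced = default_timing_dag()
    del reduced.edges[("complete_sahara_south", "depart_west_africa")]
    hits = 0
    for s in range(n_power):
        cfg = SimConfig(n_birds=137, n_years=1,
                        seed=(seed * 104_729 + s) % (2**31 - 1),
                        mortality_enabled=False)
        data = _standardized(truth_milestone_table(simulate_schedules(cfg)),
                             dag)
        claims = dsep_test(reduced, data)["claims"]
        row = claims[(claims["independent"] == "complete_sahara_south")
                     & (claims["dependent"] == "depart_west_africa")]
        hits += bool(len(row) and row["p"].iloc[0] < 0.01)
    return dict(fishers_c_ks_p=ks_p,
                omitted_edge_detection_pct=100.0 * hits / n_power,
                n_sims=n_sims)


def _mortality_records(rng, n, kind, slope, intercept=-1.5):
    t = rng.standard_normal(n)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(intercept + slope * t)))
         ).astype(int)
    return pd.DataFrame(dict(
        bird_id=[f"b{i}" for i in range(n)],
        cycle_id=[f"b{i}-{kind}" for i in range(n)], kind=kind, timing=t,
        habitat=np.where(rng.integers(0, 2, n) == 1, "upland", "lowland"),
        route=np.where(rng.integers(0, 2, n) == 1, "SE", "SW"),
        died_next_stage=y))


def mortality_calibration_study(seed: int = 1, n_null: int = 100) -> dict:
    """Pooled timing->mortality model: recovery of a shared generating
    slope of -1.5 over the three pooled milestones (n = 300), and the rate
    at which a null slope is called non-zero at the 0.95 level."""
    kinds = ("complete_sahara_south", "depart_west_africa",
             "arrive_breeding")
    rng = np.random.default_rng(seed)
    per_kind = {k: _mortality_records(rng, 100, k, -1.5) for k in kinds}
    mc = MCMCSettings(chains=2, burn_in=500, draws=1500, seed=seed)
    pooled = combined_milestones_fit(per_kind, mcmc=mc)
    d = pooled.draws("timing").ravel()
    slope_z = abs(d.mean() - (-1.5)) / d.std()

    mc_null = MCMCSettings(chains=2, burn_in=300, draws=700, seed=seed)
    false_calls = 0
    for rep in range(n_null):
        rng = np.random.default_rng((seed * 15_485_863 + rep) % (2**31 - 1))
        per_kind = {k: _mortality_records(rng, 100, k, 0.0) for k in kinds}
        fit = combined_milestones_fit(per_kind, mcmc=mc_null)
        false_calls += fit.p_nonzero("timing") >= 0.95
    return dict(pooled_slope_mean=float(d.mean()),
                pooled_slope_sd=float(d.std()),
                pooled_slope_z=float(slope_z),
                null_slope_false_call_pct=100.0 * false_calls / n_null,
                n_null=n_null)
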