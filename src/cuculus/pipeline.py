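"""Stage orchestration shared by the command-line interface and the
numbered analysis drivers.

Every stage is a pure function of (inputs, config, seed) writing
deterministic artifact paths under the configured output directory, with a
structured log of counts in/out so a run can be audited (how many
milestones from how many cycles for how many birds).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, milestones as ms, path_mortality, path_timing, repeatability
from .config import RunConfig
from .dag import MILESTONES, default_timing_dag
from .mcmc import MCMCSettings
from .synthetic import (SimConfig, deaths_table, metadata_table,
                        render_population, simulate_schedules,
                        truth_milestone_table)

log = logging.getLogger("cuculus")

BINARY_CODING = {"habitat": "upland", "route": "SE"}


def _out(cfg: RunConfig, name: str) -> Path:
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    return cfg.output_dir / name


def run_simulate(cfg: RunConfig) -> dict:
    sim = SimConfig(seed=cfg.seed, **cfg.simulate)
    records = simulate_schedules(sim)
    fixes = render_population(records, sim)
    meta = metadata_table(records)
    truth = truth_milestone_table(records, start_year=sim.start_year)
    deaths = deaths_table(records, start_year=sim.start_year)
    io.write_fixes(fixes, _out(cfg, "fixes.csv"))
    meta.to_csv(_out(cfg, "metadata.csv"), index=False)
    truth.to_csv(_out(cfg, "truth_milestones.csv"), index=False)
    deaths.to_csv(_out(cfg, "deaths.csv"), index=False)
    log.info("simulate: %d birds, %d bird-years, %d fixes, %d deaths",
             meta.shape[0], truth.shape[0], fixes.shape[0], deaths.shape[0])
    return dict(records=records, fixes=fixes, meta=meta, truth=truth,
                deaths=deaths, sim=sim)


def run_segment(cfg: RunConfig, fixes: pd.DataFrame | None = None) -> dict:
    from .segmentation import segment
    if fixes is None:
        fixes = io.read_fixes(cfg.fixes or _out(cfg, "fixes.csv"))
    th = cfg.thresholds
    cyc, best, stops = segment(
        fixes, gap_hours=th["cycle_gap_h"], radius_km=th["stopover_km"],
        min_days=th["min_duration_days"])
    io.write_stopovers(stops, _out(cfg, "stopovers.csv"))
    log.info("segment: %d fixes -> %d cycles -> %d stopovers",
             len(fixes), best.shape[0], stops.shape[0])
    return dict(fixes=cyc, best=best, stopovers=stops)


def run_milestones(cfg: RunConfig, fixes=None, stopovers=None,
                   meta=None) -> dict:
    regions = io.read_regions(cfg.regions)
    if fixes is None:
        fixes = io.read_fixes(cfg.fixes or _out(cfg, "fixes.csv"))
    if stopovers is None:
        stopovers = io.read_stopovers(_out(cfg, "stopovers.csv"))
    if meta is None:
        meta = pd.read_csv(cfg.metadata or _out(cfg, "metadata.csv"))
    th = cfg.thresholds
    raw = ms.extract_milestones(stopovers, fixes, regions, meta,
                                breeding_disc_km=th["breeding_disc_km"])
    retained = ms.filter_uncertain(raw, threshold=th["uncertainty_max_days"])
    full, repeat = ms.build_datasets(retained)
    anomalies = ms.within_individual_anomaly(retained)
    io.write_milestones(retained, _out(cfg, "milestones.csv"))
    anomalies.to_csv(_out(cfg, "anomalies.csv"), index=False)
    n_cycles = full["cycle_id"].nunique() if len(full) else 0
    n_birds = full["bird_id"].nunique() if len(full) else 0
    log.info("milestones: %d extracted, %d retained after the 5-day "
             "uncertainty filter -- %d milestones from %d migratory cycles "
             "for %d birds; repeat dataset: %d rows",
             len(raw), len(retained), len(full), n_cycles, n_birds,
             len(repeat))
    return dict(raw=raw, retained=retained, full=full, repeat=repeat,
                anomalies=anomalies, meta=meta, regions=regions)


def run_repeatability(cfg: RunConfig, full: pd.DataFrame | None = None,
                      mcmc: MCMCSettings | None = None) -> dict:
    if full is None:
        full = io.read_milestones(_out(cfg, "milestones.csv"))
    mcmc = mcmc or cfg.mcmc
    per_ms = {}
    variances = {}
    for kind in MILESTONES:
        sub = full[full["kind"] == kind]
        if sub["bird_id"].nunique() < 2 or len(sub) < 3:
            continue
        counts = sub.groupby("bird_id").size()
        if counts.max() < 2:
            continue
        variances[kind] = repeatability.milestone_variance(
            sub["date_cycle_days"].to_numpy())
        per_ms[kind] = repeatability.fit_variance_components(
            sub["date_cycle_days"].to_numpy(), sub["bird_id"].to_numpy(),
            mcmc=mcmc)
    summary = repeatability.repeatability_summary(per_ms) if per_ms else {}
    ftests = repeatability.consecutive_variance_tests(full, MILESTONES)
    result = dict(
        variances=variances,
        repeatability={k: v.summary() for k, v in per_ms.items()},
        summary=summary,
        f_tests=ftests.to_dict(orient="records"))
    io.write_json(result, _out(cfg, "repeatability.json"))
    for kind, v in per_ms.items():
        if not v.converged:
            log.warning("repeatability[%s]: Rhat above 1.1, flagged", kind)
    log.info("repeatability: %d milestones fitted", len(per_ms))
    return dict(fits=per_ms, **result)


def timing_model_data(full: pd.DataFrame, meta: pd.DataFrame,
                      stopovers: pd.DataFrame | None = None,
                      regions=None) -> pd.DataFrame:
    """Standardized wide table for the timing path model.

    Stopover-location covariates (last European pre-Sahara stopover
    latitude, last West African stopover longitude) are derived from the
    detected stopovers when available.  Columns with fewer than two
    distinct observed values are left unstandardized (all-missing columns
    are imputed by the sampler under a unit-normal prior).
    """
    dag = default_timing_dag()
    wide = ms.milestone_wide_table(full, meta)
    if stopovers is not None and regions is not None and len(full):
        cov = ms.stopover_covariates(stopovers, full, regions)
        wide = wide.merge(cov, on="cycle_id", how="left")
    wide = path_timing.encode_binary(wide, BINARY_CODING)
    for c in dag.all_nodes():
        if c not in wide.columns:
            wide[c] = np.nan
    cols = [c for c in dag.all_nodes()
            if wide[c].dropna().nunique() >= 2]
    return path_timing.standardize(wide, cols)


def run_path_timing(cfg: RunConfig, full=None, meta=None, stopovers=None,
                    mcmc: MCMCSettings | None = None) -> dict:
    if full is None:
        full = io.read_milestones(_out(cfg, "milestones.csv"))
    if meta is None:
        meta = pd.read_csv(cfg.metadata or _out(cfg, "metadata.csv"))
    if stopovers is None:
        spath = _out(cfg, "stopovers.csv")
        stopovers = io.read_stopovers(spath) if spath.exists() else None
    mcmc = mcmc or cfg.mcmc
    dag = default_timing_dag()
    regions = io.read_regions(cfg.regions)
    data = timing_model_data(full, meta, stopovers=stopovers,
                             regions=regions)
    fit = path_timing.fit_path_model(data, dag, mcmc=mcmc)
    table = path_timing.summarize_paths(fit)
    dsep = path_timing.dsep_test(dag, data)
    table.to_csv(_out(cfg, "path_timing.csv"), index=False)
    io.write_json(dict(
        rhat=fit.rhat, converged=fit.converged, n=fit.n,
        dsep=dict(C=dsep["C"], df=dsep["df"], p=dsep["p"]),
        node_r2={v: fit.node_r2(v) for v in dag.endogenous}),
        _out(cfg, "path_timing.json"))
    log.info("path-timing: n=%d cycles, converged=%s, Fisher's C p=%.3f",
             fit.n, fit.converged, dsep["p"])
    return dict(fit=fit, table=table, dsep=dsep, data=data, dag=dag)


def run_path_mortality(cfg: RunConfig, full=None, meta=None, deaths=None,
                       mcmc: MCMCSettings | None = None) -> dict:
    if full is None:
        full = io.read_milestones(_out(cfg, "milestones.csv"))
    if meta is None:
        meta = pd.read_csv(cfg.metadata or _out(cfg, "metadata.csv"))
    if deaths is None:
        dpath = cfg.deaths or _out(cfg, "deaths.csv")
        deaths = pd.read_csv(dpath) if Path(dpath).exists() else pd.DataFrame()
    mcmc = mcmc or cfg.mcmc
    per_kind = path_mortality.build_mortality_dataset(full, deaths, meta)
    fits = {}
    for kind, records in per_kind.items():
        if len(records) < 10:
            log.info("path-mortality[%s]: only %d records, skipped",
                     kind, len(records))
            continue
        fits[kind] = path_mortality.fit_mortality_model(records, mcmc=mcmc)
    combined = None
    try:
        combined = path_mortality.combined_milestones_fit(per_kind, mcmc=mcmc)
    except ValueError:
        log.warning("path-mortality: pooled fit not possible (no records)")
    out = {kind: f.summary() for kind, f in fits.items()}
    if combined is not None:
        out["combined"] = combined.summary()
    io.write_json(out, _out(cfg, "path_mortality.json"))
    log.info("path-mortality: %d per-milestone fits%s", len(fits),
             ", plus pooled fit" if combined is not None else "")
    return dict(per_kind=per_kind, fits=fits, combined=combined, summary=out)


def run_report(cfg: RunConfig, results: dict | None = None) -> str:
    """Plain-text summary: milestone ledger, repeatability table,
    supported-paths listing."""
    lines = ["cuculus run report", "=" * 40]
    mpath = _out(cfg, "milestones.csv")
    if mpath.exists():
        full = io.read_milestones(mpath)
        lines.append(f"{len(full)} milestones from "
                     f"{full['cycle_id'].nunique()} migratory cycles for "
                     f"{full['bird_id'].nunique()} birds")
    rpath = _out(cfg, "repeatability.json")
    if rpath.exists():
        import json
        rep = json.loads(rpath.read_text())
        if rep.get("summary"):
            lines.append("")
            lines.append("repeatability (median, 95% interval):")
            for kind, row in rep["summary"]["milestones"].items():
                lines.append(f"  {kind:24s} {row['estimate']:.2f} "
                             f"[{row['lower']:.2f}, {row['upper']:.2f}]")
            s = rep["summary"]
            lines.append(f"  mean {s['mean']:.2f}, range "
                         f"{s['min']:.2f}-{s['max']:.2f}")
    ppath = _out(cfg, "path_timing.csv")
    if ppath.exists():
        table = pd.read_csv(ppath)
        lines.append("")
        lines.append("supported paths (p >= 0.80):")
        for _, r in table[table["headline"]].iterrows():
            lines.append(f"  {r['path']:50s} {r['coefficient']:+.3f} "
                         f"(p={r['probability']:.2f}, {r['tier']})")
    text = "\n".join(lines) + "\n"
    _out(cfg, "report.txt").write_text(text)
    return text


def run_all(cfg: RunConfig) -> dict:
    sim = run_simulate(cfg)
    seg = run_segment(cfg, fixes=io.read_fixes(_out(cfg, "fixes.csv")))
    mst = run_milestones(cfg, fixes=seg["fixes"], stopovers=seg["stopovers"],
                         meta=sim["meta"])
    rep = run_repeatability(cfg, full=mst["full"])
    pt = run_path_timing(cfg, full=mst["full"], meta=sim["meta"],
                         stopovers=seg["stopovers"])
    pm = run_path_mortality(cfg, full=mst["full"], meta=sim["meta"],
                            deaths=sim["deaths"])
    report = run_report(cfg)
    return dict(simulate=sim, segment=seg, milestones=mst, repeatability=rep,
                path_timing=pt, path_mortality=pm, report=report)
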