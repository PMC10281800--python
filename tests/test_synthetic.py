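import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cuculus.dag import DagSpec, ExoVar, MILESTONES, null_dag
from cuculus.geometry import is_south_of
from cuculus.synthetic import (DEFAULT_MILESTONE_MU, SimConfig,
                               noise_free, render_population, render_track,
                               simulate_schedules, truth_milestone_table)


def _dates_frame(records):
    return pd.DataFrame([r.dates for r in records])


class TestSchedules:
    def test_seeded_runs_are_bit_reproducible(self):
        cfg = SimConfig(n_birds=6, n_years=2, seed=99)
        a = render_population(simulate_schedules(cfg), cfg)
        b = render_population(simulate_schedules(cfg), cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_milestones_strictly_increasing_within_cycle(self):
        cfg = SimConfig(n_birds=40, n_years=3, seed=4)
        for r in simulate_schedules(cfg):
            d = [r.dates[m] for m in MILESTONES]
            assert all(x < y for x, y in zip(d[:-1], d[1:]))

    def test_null_model_dates_iid_around_intercepts(self):
        cfg = SimConfig(n_birds=400, n_years=1, seed=2, dag=null_dag(),
                        mortality_enabled=False)
        df = _dates_frame(simulate_schedules(cfg))
        for m in MILESTONES:
            se = cfg.milestone_scale[m] / np.sqrt(len(df))
            assert df[m].mean() == pytest.approx(DEFAULT_MILESTONE_MU[m],
                                                 abs=4 * se)
        # no induced correlation between consecutive milestones (the
        # monotonicity redraw touches only far tails)
        r = np.corrcoef(df["complete_sahara_south"],
                        df["depart_west_africa"])[0, 1]
        assert abs(r) < 0.12

    def test_single_edge_coefficient_recovered_by_ols(self):
        # crossing -> West-Africa departure at 0.52 (R^2 ~ 0.27)
        dag = DagSpec(
            exogenous={"habitat": ExoVar(kind="binary"),
                       "route": ExoVar(kind="binary")},
            edges={("complete_sahara_south", "depart_west_africa"): 0.52},
            between_fraction={m: 0.0 for m in MILESTONES})
        cfg = SimConfig(n_birds=300, n_years=1, seed=8, dag=dag,
                        mortality_enabled=False)
        df = _dates_frame(simulate_schedules(cfg))
        x = (df["complete_sahara_south"] - df["complete_sahara_south"].mean()) \
            / df["complete_sahara_south"].std(ddof=0)
        y = (df["depart_west_africa"] - df["depart_west_africa"].mean()) \
            / df["depart_west_africa"].std(ddof=0)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(res.params.iloc[1] - 0.52) < 3 * res.bse.iloc[1]

    def test_between_individual_variance_ratio_at_half_repeatability(self):
        from cuculus.dag import calibrate_between_fraction, default_timing_dag
        dag = default_timing_dag()
        calibrate_between_fraction(dag, "arrive_winter", 0.5)
        cfg = SimConfig(n_birds=200, n_years=4, seed=14, dag=dag,
                        mortality_enabled=False)
        df = pd.DataFrame([dict(bird=r.bird_id, d=r.dates["arrive_winter"])
                           for r in simulate_schedules(cfg)])
        within = df.groupby("bird")["d"].var(ddof=1).mean()
        between = df.groupby("bird")["d"].mean().var(ddof=1) - within / 4
        assert between / within == pytest.approx(1.0, abs=0.35)


class TestTrack:
    def test_duty_cycle_gap_structure(self, clean_population):
        fixes = clean_population["fixes"]
        cfg = clean_population["config"]
        for _, grp in fixes.groupby("bird_id"):
            gaps = grp["t"].diff().dropna().dt.total_seconds() / 3600.0
            assert (gaps > 0).all()  # strictly increasing timestamps
            # consecutive on-windows are separated by at least the off time
            assert gaps.min() >= cfg.duty_off_hours - 1e-9

    def test_expected_on_windows_in_29_days(self):
        # 29 days * 24 h / 58 h = 12 windows exactly, any phase
        cfg = noise_free(SimConfig(n_birds=3, n_years=1, seed=5,
                                   mortality_enabled=False))
        recs = simulate_schedules(cfg)
        fixes = render_population(recs, cfg)
        for r in recs:
            grp = fixes[fixes["bird_id"] == r.bird_id]
            anchor = cfg.cycle_anchor(r.year)
            lo = anchor + pd.Timedelta(days=100)
            hi = lo + pd.Timedelta(days=29)
            n = ((grp["t"] >= lo) & (grp["t"] < hi)).sum()
            assert n == 12

    def test_missed_cycles_thin_the_track(self):
        cfg = SimConfig(n_birds=4, n_years=1, seed=6, fix_noise_km=0.0,
                        p_missed_cycle=0.4, mortality_enabled=False)
        full = render_population(simulate_schedules(noise_free(cfg)),
                                 noise_free(cfg))
        thin = render_population(simulate_schedules(cfg), cfg)
        assert len(thin) < 0.8 * len(full)

    def test_death_truncates_track_north_of_the_sahara(self, regions,
                                                       mortal_population):
        cfg = mortal_population["config"]
        died_early = [r for r in mortal_population["records"]
                      if r.death_stage == "depart_breeding"]
        assert died_early, "expected at least one post-departure death"
        for r in died_early[:3]:
            track = render_track(r, cfg)
            assert len(track)
            south = [is_south_of(regions["sahara"], la, lo)
                     for la, lo in zip(track["lat"], track["lon"])]
            assert not any(south)

    def test_zero_flight_speed_with_distinct_waypoints_errors(self):
        cfg = noise_free(SimConfig(n_birds=1, n_years=1, seed=1,
                                   flight_speed_kmh=0.0,
                                   mortality_enabled=False))
        (rec,) = simulate_schedules(cfg)
        with pytest.raises(ValueError, match="flight speed"):
            render_track(rec, cfg)


class TestMortality:
    def test_impossible_mortality_means_no_deaths(self):
        logit = {m: (-50.0, 0.0) for m in MILESTONES}
        cfg = SimConfig(n_birds=60, n_years=2, seed=3, mortality_logit=logit)
        assert all(r.death_stage is None for r in simulate_schedules(cfg))

    def test_logit_zero_gives_half_probability_at_first_stage(self):
        logit = {m: (-50.0, 0.0) for m in MILESTONES}
        logit["depart_breeding"] = (0.0, 0.0)
        cfg = SimConfig(n_birds=2000, n_years=1, seed=9, mortality_logit=logit)
        recs = simulate_schedules(cfg)
        rate = np.mean([r.death_stage == "depart_breeding" for r in recs])
        assert rate == pytest.approx(0.5, abs=0.04)

    def test_logistic_regression_recovers_generating_slope(self):
        logit = {m: (-50.0, 0.0) for m in MILESTONES}
        logit["complete_sahara_south"] = (-2.0, -1.5)
        cfg = SimConfig(n_birds=2000, n_years=1, seed=10,
                        mortality_logit=logit)
        recs = simulate_schedules(cfg)
        z = np.array([r.z["complete_sahara_south"] for r in recs])
        y = np.array([r.death_stage == "complete_sahara_south"
                      for r in recs], dtype=float)
        res = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        assert abs(res.params[1] - (-1.5)) < 3 * res.bse[1]

    def test_truth_table_truncated_at_death(self, mortal_population):
        truth = truth_milestone_table(mortal_population["records"])
        died = truth[truth["death_stage"] == "complete_sahara_south"]
        assert died["arrive_winter"].isna().all()
        assert died["complete_sahara_south"].notna().all()
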