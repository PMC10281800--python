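import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cuculus.mcmc import MCMCSettings
from cuculus.path_mortality import (build_mortality_dataset,
                                    combined_milestones_fit,
                                    fit_mortality_model)
from cuculus.synthetic import (deaths_table, metadata_table,
                               truth_milestone_table)


def _records(n, slope, intercept=-1.5, seed=0, habitat_slope=0.0):
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    hab = rng.integers(0, 2, n)
    eta = intercept + slope * t + habitat_slope * hab * t
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(dict(
        bird_id=[f"b{i}" for i in range(n)],
        cycle_id=[f"b{i}-2015" for i in range(n)],
        kind="complete_sahara_south", timing=t,
        habitat=np.where(hab == 1, "upland", "lowland"),
        route=np.where(rng.integers(0, 2, n) == 1, "SE", "SW"),
        died_next_stage=y))


class TestDatasetConstruction:
    def test_truth_counts_and_exclusions(self, mortal_population):
        recs = mortal_population["records"]
        meta = mortal_population["meta"]
        truth = truth_milestone_table(recs)
        long = truth.melt(id_vars=["bird_id", "cycle_id"],
                          value_vars=[c for c in truth.columns
                                      if c.startswith(("depart", "complete",
                                                       "arrive"))],
                          var_name="kind", value_name="date_cycle_days"
                          ).dropna()
        deaths = deaths_table(recs)
        per_kind = build_mortality_dataset(long, deaths, meta)
        assert "depart_winter" not in per_kind
        for kind, df in per_kind.items():
            true_deaths = (deaths["death_after"] == kind).sum()
            assert df["died_next_stage"].sum() == true_deaths

    def test_no_deaths_all_zero(self, mortal_population):
        truth = truth_milestone_table(mortal_population["records"])
        long = truth.melt(id_vars=["bird_id", "cycle_id"],
                          value_vars=["depart_breeding"],
                          var_name="kind", value_name="date_cycle_days"
                          ).dropna()
        per_kind = build_mortality_dataset(long, pd.DataFrame(),
                                           mortal_population["meta"])
        assert per_kind["depart_breeding"]["died_next_stage"].sum() == 0

    def test_uncertain_death_dropped(self, mortal_population):
        recs = mortal_population["records"]
        deaths = deaths_table(recs)
        flagged = deaths["cycle_id"].iloc[0]
        deaths.loc[deaths["cycle_id"] == flagged, "certain"] = False
        truth = truth_milestone_table(recs)
        long = truth.melt(id_vars=["bird_id", "cycle_id"],
                          value_vars=[deaths["death_after"].iloc[0]],
                          var_name="kind", value_name="date_cycle_days"
                          ).dropna()
        per_kind = build_mortality_dataset(long, deaths,
                                           mortal_population["meta"])
        for df in per_kind.values():
            assert flagged not in set(df["cycle_id"])


class TestSingleMilestoneFit:
    def test_generating_slope_recovered(self, fast_mcmc):
        rec = _records(500, 2.0, intercept=-1.5, seed=1)
        fit = fit_mortality_model(rec, fast_mcmc)
        d = fit.draws("timing").ravel()
        assert abs(d.mean() - 2.0) < 3 * d.std()
        assert fit.converged and not fit.prior_dominated

    def test_interaction_matches_stratified_refit(self):
        mc = MCMCSettings(chains=2, burn_in=500, draws=1500, seed=5)
        rec = _records(800, 2.0, intercept=-1.2, seed=2, habitat_slope=-4.0)
        full = fit_mortality_model(rec, mc)
        lowland_contrast = full.draws("timing").ravel()
        low = rec[rec["habitat"] == "lowland"]
        strat = fit_mortality_model(low, mc, interaction=False)
        strat_d = strat.draws("timing").ravel()
        pooled_sd = np.hypot(lowland_contrast.std(), strat_d.std())
        assert abs(lowland_contrast.mean() - strat_d.mean()) < 3 * pooled_sd

    def test_all_survivors_prior_dominated_not_crash(self, fast_mcmc):
        rec = _records(60, 0.0, intercept=-50.0, seed=3)
        rec["died_next_stage"] = 0
        fit = fit_mortality_model(rec, fast_mcmc)
        assert fit.prior_dominated

    def test_within_stratum_effects_reported(self, fast_mcmc):
        rec = _records(300, 1.0, seed=4)
        s = fit_mortality_model(rec, fast_mcmc).summary()
        assert "timing_lowland" in s["coefficients"]
        assert "timing_upland" in s["coefficients"]
        assert "habitat" in s["timing_model"]


class TestCombinedFit:
    def test_identical_groups_match_single_group_slope(self):
        mc = MCMCSettings(chains=2, burn_in=400, draws=1000, seed=6)
        base = _records(300, -1.5, seed=7)
        per_kind = {}
        for k in ("complete_sahara_south", "depart_west_africa",
                  "arrive_breeding"):
            d = base.copy()
            d["kind"] = k
            per_kind[k] = d
        pooled = combined_milestones_fit(per_kind, mcmc=mc)
        single = fit_mortality_model(base, mc, interaction=False)
        pd_, sd_ = pooled.draws("timing").ravel(), single.draws("timing").ravel()
        assert abs(pd_.mean() - sd_.mean()) < 3 * np.hypot(pd_.std(), sd_.std())

    def test_pooled_reduces_to_single_when_others_empty(self):
        mc = MCMCSettings(chains=2, burn_in=400, draws=1000, seed=8)
        per_kind = {"complete_sahara_south": _records(250, -1.5, seed=9)}
        pooled = combined_milestones_fit(per_kind, mcmc=mc)
        assert pooled.names == ["intercept[complete_sahara_south]", "timing"]
        d = pooled.draws("timing").ravel()
        assert abs(d.mean() - (-1.5)) < 3 * d.std() + 0.5

    def test_all_survivor_group_still_estimable_via_pooling(self, fast_mcmc):
        a = _records(200, -1.5, seed=10)
        b = _records(120, -1.5, seed=11)
        b["died_next_stage"] = 0
        b["kind"] = "depart_west_africa"
        pooled = combined_milestones_fit(
            {"complete_sahara_south": a, "depart_west_africa": b},
            mcmc=fast_mcmc)
        assert not pooled.prior_dominated
        assert np.isfinite(pooled.draws("timing")).all()

    def test_no_records_raises(self, fast_mcmc):
        with pytest.raises(ValueError):
            combined_milestones_fit({}, mcmc=fast_mcmc)
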