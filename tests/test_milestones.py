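import numpy as np
import pandas as pd
import pytest

from cuculus.dag import MILESTONES
from cuculus.io import read_regions
from cuculus.milestones import (build_datasets, classify_route,
                                extract_milestones, filter_uncertain,
                                milestone_uncertainty,
                                repeat_group_histogram,
                                within_individual_anomaly)
from cuculus.segmentation import segment
from cuculus.synthetic import (SimConfig, metadata_table, noise_free,
                               render_population, simulate_schedules)
from conftest import make_fix_frame


@pytest.fixture(scope="module")
def extracted(clean_population, regions):
    pop = clean_population
    return extract_milestones(pop["stopovers"], pop["fixes"], regions,
                              pop["meta"])


class TestExtraction:
    def test_recovery_within_one_duty_cycle_of_truth(self, extracted,
                                                     clean_population):
        cfg = clean_population["config"]
        recs = {(r.bird_id, cfg.start_year + r.year): r
                for r in clean_population["records"]}
        n_matched = 0
        for _, row in extracted.iterrows():
            year = int(row["cycle_id"].split("-")[1])
            rec = recs.get((row["bird_id"], year))
            assert rec is not None
            err_h = abs(row["date_cycle_days"] - rec.dates[row["kind"]]) * 24
            assert err_h <= 58.0, (row["cycle_id"], row["kind"], err_h)
            n_matched += 1
        assert n_matched >= 0.95 * len(clean_population["records"]) * 6

    def test_dates_monotone_within_each_cycle(self, extracted):
        order = {k: i for i, k in enumerate(MILESTONES)}
        for _, grp in extracted.groupby("cycle_id"):
            g = grp.sort_values("date_cycle_days")
            ranks = [order[k] for k in g["kind"]]
            assert ranks == sorted(ranks)

    def test_death_truncates_milestones(self, regions):
        cfg = SimConfig(n_birds=20, n_years=2, seed=31, fix_noise_km=0.0,
                        p_missed_cycle=0.0)
        recs = simulate_schedules(cfg)
        died = [r for r in recs if r.death_stage in MILESTONES[:3]]
        assert died
        fixes = render_population(recs, cfg)
        _, _, stops = segment(fixes)
        mil = extract_milestones(stops, fixes, regions, metadata_table(recs))
        order = {k: i for i, k in enumerate(MILESTONES)}
        for r in died:
            cyc = f"{r.bird_id}-{cfg.start_year + r.year}"
            kinds = mil.loc[mil["cycle_id"] == cyc, "kind"]
            assert all(order[k] <= order[r.death_stage] for k in kinds)

    def test_hand_placed_sahara_straddle_dates_the_crossing(self, regions):
        # southbound: fixes north of, then south of, the Sahara
        fx = make_fix_frame([0, 58, 116, 174],
                            [25.0, 20.0, 12.0, 11.8],
                            [0.0, 0.0, 0.0, 0.0],
                            t0="2015-08-01T00:00:00Z")
        meta = pd.DataFrame([dict(bird_id="B1", breeding_lat=52.0,
                                  breeding_lon=-1.0)])
        _, _, stops = segment(fx)
        mil = extract_milestones(stops, fx, regions, meta)
        m2 = mil[mil["kind"] == "complete_sahara_south"]
        assert len(m2) == 1
        assert m2["t"].iloc[0] == fx["t"].iloc[2]


class TestUncertainty:
    def _milestone(self, kind, basis_h, bird="B1"):
        t0 = pd.Timestamp("2015-06-01T00:00:00Z")
        return pd.Series(dict(bird_id=bird, kind=kind,
                              basis_t=t0 + pd.Timedelta(hours=basis_h)))

    def test_departure_gap_to_next_fix(self, regions):
        fx = make_fix_frame([0, 3.2 * 24], [50, 50], [0, 0])
        m = self._milestone("depart_winter", 0)
        assert milestone_uncertainty(m, fx, regions) == pytest.approx(3.2)

    def test_arrival_gap_to_previous_fix(self, regions):
        fx = make_fix_frame([0, 4.8], [50, 50], [0, 0])
        m = self._milestone("arrive_winter", 4.8)
        assert milestone_uncertainty(m, fx, regions) == pytest.approx(0.2)

    def test_sahara_based_west_africa_departure_is_two_days(self, regions):
        # basis fix inside the Sahara, 6-day gap to the next fix
        fx = make_fix_frame([0, 6 * 24], [22.0, 45.0], [0.0, 2.0])
        m = self._milestone("depart_west_africa", 0)
        assert milestone_uncertainty(m, fx, regions) == 2.0

    def test_west_africa_departure_outside_sahara_uses_gap(self, regions):
        fx = make_fix_frame([0, 6 * 24], [9.0, 22.0], [-5.0, -2.0])
        m = self._milestone("depart_west_africa", 0)
        assert milestone_uncertainty(m, fx, regions) == pytest.approx(6.0)


class TestFilter:
    def _frame(self, uncertainties):
        return pd.DataFrame(dict(
            bird_id="B1", cycle_id="B1-2015", kind="arrive_winter",
            date_cycle_days=150.0, uncertainty_days=uncertainties))

    def test_strictly_above_five_days_excluded(self):
        out = filter_uncertain(self._frame([4.9, 5.0, 5.1]))
        assert sorted(out["uncertainty_days"]) == [4.9, 5.0]

    def test_empty_input_empty_output(self):
        assert len(filter_uncertain(self._frame([]))) == 0

    def test_filtering_monotone_in_threshold(self):
        rng = np.random.default_rng(17)
        df = self._frame(list(rng.exponential(4.0, 200)))
        kept5 = set(filter_uncertain(df, 5.0).index)
        kept7 = set(filter_uncertain(df, 7.0).index)
        n_direct = int((df["uncertainty_days"] <= 5.0).sum())
        assert len(kept5) == n_direct
        assert kept5 <= kept7


class TestRoute:
    def test_fix_inside_iberia_is_southwest(self, regions):
        fx = make_fix_frame([0], [40.0], [-4.0])
        assert classify_route(fx, regions) == "SW"

    def test_chord_over_italy_is_southeast(self, regions):
        fx = make_fix_frame([0, 58], [46.0, 40.0], [5.0, 12.0])
        assert classify_route(fx, regions) == "SE"

    def test_carry_forward_from_previous_year(self, regions):
        fx = make_fix_frame([0, 58], [52.0, 51.0], [-1.0, -1.0])
        assert classify_route(fx, regions, "SW") == "SW"
        assert classify_route(fx, regions) == "unclassified"


class TestAnomaliesAndDatasets:
    def _long(self, entries):
        return pd.DataFrame(
            [dict(bird_id=b, cycle_id=f"{b}-{y}", kind=k,
                  date_cycle_days=d, uncertainty_days=1.0)
             for b, y, k, d in entries])

    def test_two_year_anomalies_symmetric(self):
        mil = self._long([("B1", 2015, "arrive_winter", 100),
                          ("B1", 2016, "arrive_winter", 104)])
        out = within_individual_anomaly(mil)
        assert sorted(out["anomaly_days"]) == [-2.0, 2.0]

    def test_three_year_anomalies_centered(self):
        mil = self._long([("B1", y, "arrive_winter", d)
                          for y, d in [(2015, 10), (2016, 20), (2017, 30)]])
        out = within_individual_anomaly(mil)
        assert sorted(out["anomaly_days"]) == [-10.0, 0.0, 10.0]

    def test_single_year_bird_excluded_from_repeat_dataset(self):
        mil = self._long([("B1", 2015, "arrive_winter", 100),
                          ("B2", 2015, "arrive_winter", 90),
                          ("B2", 2016, "arrive_winter", 95)])
        full, repeat = build_datasets(mil)
        assert len(full) == 3
        assert set(repeat["bird_id"]) == {"B2"}

    def test_only_repeated_kinds_enter_repeat_dataset(self):
        mil = self._long([("B1", 2015, "arrive_winter", 100),
                          ("B1", 2016, "arrive_winter", 105),
                          ("B1", 2015, "depart_winter", 250),
                          ("B1", 2016, "depart_winter", 260),
                          ("B1", 2015, "depart_breeding", 30)])
        _, repeat = build_datasets(mil)
        assert set(repeat["kind"]) == {"arrive_winter", "depart_winter"}

    def test_all_single_year_gives_empty_repeat(self):
        mil = self._long([("B1", 2015, "arrive_winter", 100),
                          ("B2", 2015, "depart_winter", 250)])
        _, repeat = build_datasets(mil)
        assert len(repeat) == 0

    def test_anomalies_sum_to_zero_per_group_on_synthetic(self, regions,
                                                          extracted):
        out = within_individual_anomaly(extracted.assign(retained_flag=True))
        sums = out.groupby(["bird_id", "kind"])["anomaly_days"].sum()
        assert np.allclose(sums, 0.0, atol=1e-9)

    def test_repeat_histogram_matches_truth(self, extracted,
                                            clean_population):
        _, repeat = build_datasets(extracted)
        hist = repeat_group_histogram(repeat)
        # every bird in the clean population survives both years, so each
        # repeated bird-kind group contributes exactly 2 cycles
        assert list(hist.index) == [2]
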