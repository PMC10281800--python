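"""Synthetic migrant generator.

Produces populations of simulated male cuckoos: true annual schedules drawn
from a linear-Gaussian DAG with individual random intercepts, stage-wise
Bernoulli mortality whose log-odds depend on standardized milestone timing,
and duty-cycled satellite fixes rendered along great-circle routes between
stopover waypoints.  Every downstream stage of the pipeline is testable
against the truth tables this module emits.

Dates are expressed as continuous days since 1 June of the cycle's starting
year ("cycle time"), so all six milestones are monotone within a cycle and
never wrap at New Year.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dag import MILESTONES, DagSpec, default_timing_dag
from .geometry import (destination_offset_km, great_circle_interpolate,
                       great_circle_points, haversine_km)

HOURS_PER_DAY = 24.0

#: Default true schedule: mean cycle-day and population SD (days) of each
#: milestone.  Means follow the cuckoo annual cycle (departure from the UK
#: around 1 July, southbound Sahara crossing in mid August, arrival in the
#: Congo-basin winter quarters in November, northward departure in early
#: March, departure from the West African stopover in April and breeding-
#: grounds arrival in mid May).  SDs echo the reported pattern of timing
#: variation: largest around the wintering grounds (variance ~600 days²)
#: and smallest at departure from West Africa (~78 days²).
DEFAULT_MILESTONE_MU = {
    "depart_breeding": 30.0,
    "complete_sahara_south": 75.0,
    "arrive_winter": 160.0,
    "depart_winter": 270.0,
    "depart_west_africa": 315.0,
    "arrive_breeding": 350.0,
}
DEFAULT_MILESTONE_SCALE = {
    "depart_breeding": 15.0,
    "complete_sahara_south": 18.0,
    "arrive_winter": 24.6,
    "depart_winter": 22.0,
    "depart_west_africa": 8.8,
    "arrive_breeding": 9.4,
}

#: Minimum feasible gap (days) between consecutive milestones, set by the
#: flight time of the intervening leg at the default flight speed.
MIN_GAPS = {
    ("depart_breeding", "complete_sahara_south"): 5.0,
    ("complete_sahara_south", "arrive_winter"): 6.0,
    ("arrive_winter", "depart_winter"): 5.0,
    ("depart_winter", "depart_west_africa"): 4.0,
    ("depart_west_africa", "arrive_breeding"): 5.0,
}

#: Stage-wise mortality on the logit scale: intercept and slope on the
#: standardized true date of the milestone just passed.  Late departure from
#: the breeding grounds raises mortality (slope +2); early birds die more
#: after the three stages that most advance breeding-grounds arrival
#: (slope -1.5 after the southbound crossing, West-Africa departure and
#: breeding arrival).
DEFAULT_MORTALITY_LOGIT = {
    "depart_breeding": (-2.2, 2.0),
    "complete_sahara_south": (-2.2, -1.5),
    "arrive_winter": (-2.5, 0.0),
    "depart_winter": (-3.5, 0.0),
    "depart_west_africa": (-2.2, -1.5),
    "arrive_breeding": (-2.2, -1.5),
}

UPLAND_SITES = ["Skye & Lochalsh", "the Trossachs", "Forest of Bowland",
                "North York Moors", "Wales", "Dartmoor"]
LOWLAND_SITES = ["Sherwood Forest", "Norfolk Broads", "Thetford Forest",
                 "Worcestershire", "South Downs", "New Forest"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic population."""

    n_birds: int = 60
    n_years: int = 3
    duty_on_hours: float = 10.0
    duty_off_hours: float = 48.0
    p_missed_cycle: float = 0.15
    fix_noise_km: float = 1.5
    flight_speed_kmh: float = 50.0
    dag: DagSpec = field(default_factory=default_timing_dag)
    milestone_mu: dict = field(default_factory=lambda: dict(DEFAULT_MILESTONE_MU))
    milestone_scale: dict = field(default_factory=lambda: dict(DEFAULT_MILESTONE_SCALE))
    mortality_logit: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY_LOGIT))
    mortality_enabled: bool = True
    start_year: int = 2012
    fixes_per_window: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_missed_cycle <= 1.0:
            raise ValueError("p_missed_cycle must lie in [0,1]")
        if self.fix_noise_km < 0:
            raise ValueError("fix_noise_km must be >= 0")
        if self.duty_on_hours + self.duty_off_hours <= 0:
            raise ValueError("duty cycle length must be positive")
        for k, v in self.milestone_scale.items():
            if v < 0:
                raise ValueError(f"milestone_scale[{k!r}] must be >= 0")

    @property
    def cycle_length_hours(self) -> float:
        return self.duty_on_hours + self.duty_off_hours

    def cycle_anchor(self, year_index: int) -> pd.Timestamp:
        return pd.Timestamp(year=self.start_year + year_index, month=6, day=1,
                            tz="UTC")


@dataclass
class TrueRecord:
    """Ground truth for one bird-year (one migratory cycle)."""

    bird_id: str
    year: int                      # cycle index, 0-based
    dates: dict                    # kind -> cycle-time days (full schedule)
    z: dict                        # kind -> standardized timing
    death_stage: str | None        # kind after which the bird died, or None
    death_time: float | None       # cycle-time days
    habitat: str                   # "upland" | "lowland"
    route: str                     # "SW" | "SE"
    tagging_site: str
    breeding_lat: float
    breeding_lon: float
    eu_stopover_lat: float
    wa_stopover_lon: float
    exo_z: dict = field(default_factory=dict)
    waypoints: dict = field(default_factory=dict)

    def observed_milestones(self) -> dict:
        """Milestones actually reached (truncated at death)."""
        if self.death_stage is None:
            return dict(self.dates)
        upto = MILESTONES.index(self.death_stage)
        return {k: self.dates[k] for k in MILESTONES[: upto + 1]}


def _standardized_binary(x: int, p: float) -> float:
    return (x - p) / np.sqrt(p * (1 - p))


def simulate_schedules(config: SimConfig) -> list[TrueRecord]:
    """Draw true milestone schedules for every bird-year.

    Each milestone's standardized timing is a linear combination of its DAG
    parents plus a bird-level random intercept and year-level residual
    noise; dates are ``mu + scale * z``.  Bird-years whose dates violate
    the minimum feasible inter-milestone gaps are redrawn (year-level terms
    only, up to 100 tries) and clamped as a last resort.  A bird that dies
    contributes no further cycles.
    """
    dag = config.dag
    dag.validate()
    resid = dag.residual_sds()
    order = dag.topological_endogenous()
    rng = np.random.default_rng(config.seed)
    records: list[TrueRecord] = []
    for b in range(config.n_birds):
        bird_id = f"CK{b:03d}"
        habitat = int(rng.random() < dag.exogenous["habitat"].p) if "habitat" in dag.exogenous else 0
        route = int(rng.random() < dag.exogenous["route"].p) if "route" in dag.exogenous else 0
        site = (UPLAND_SITES if habitat else LOWLAND_SITES)[int(rng.integers(0, 6))]
        z_blat = float(rng.standard_normal())
        z_blon = float(rng.standard_normal())
        breeding_lat = float(np.clip(54.0 + 1.8 * z_blat, 50.5, 58.5))
        breeding_lon = float(np.clip(-3.0 + 2.0 * z_blon, -7.5, 1.5))
        intercepts = {m: float(rng.standard_normal() * resid[m][0]) for m in order}
        winter_lat = float(np.clip(-2.0 + 1.5 * rng.standard_normal(), -7.5, 3.5))
        winter_lon = float(np.clip(20.0 + 3.0 * rng.standard_normal(), 8.5, 31.5))
        alive = True
        for y in range(config.n_years):
            if not alive:
                break
            z_exo_bird = {
                "habitat": _standardized_binary(habitat, dag.exogenous["habitat"].p)
                if "habitat" in dag.exogenous else 0.0,
                "route": _standardized_binary(route, dag.exogenous["route"].p)
                if "route" in dag.exogenous else 0.0,
                "breeding_lat": z_blat,
                "breeding_lon": z_blon,
            }
            dates, z, exo_z = _draw_schedule(config, dag, order, resid,
                                             intercepts, z_exo_bird, rng)
            death_stage = simulate_mortality_z(z, config, rng)
            death_time = None
            if death_stage is not None:
                k = MILESTONES.index(death_stage)
                t0 = dates[death_stage]
                t1 = dates[MILESTONES[k + 1]] if k + 1 < len(MILESTONES) else t0 + 30.0
                death_time = float(rng.uniform(t0, t1))
                alive = False
            eu_lat = float(np.clip(
                (40.0 if route == 0 else 41.5) + 1.2 * exo_z["eu_stopover_lat"],
                36.5 if route == 0 else 38.5, 43.4 if route == 0 else 45.0))
            wa_lon = float(np.clip(-5.0 + 3.0 * exo_z["wa_stopover_lon"], -16.5, 9.5))
            records.append(TrueRecord(
                bird_id=bird_id, year=y, dates=dates, z=z,
                death_stage=death_stage, death_time=death_time,
                habitat="upland" if habitat else "lowland",
                route="SE" if route else "SW", tagging_site=site,
                breeding_lat=breeding_lat, breeding_lon=breeding_lon,
                eu_stopover_lat=eu_lat, wa_stopover_lon=wa_lon,
                exo_z={**z_exo_bird, **exo_z},
                waypoints={"winter": (winter_lat, winter_lon)},
            ))
    return records


def _draw_schedule(config, dag, order, resid, intercepts, z_exo_bird, rng):
    mu, scale = config.milestone_mu, config.milestone_scale
    for attempt in range(100):
        exo_year = {"eu_stopover_lat": float(rng.standard_normal()),
                    "wa_stopover_lon": float(rng.standard_normal())}
        z_all = {**z_exo_bird, **exo_year}
        z = {}
        for m in order:
            val = intercepts[m] + float(rng.standard_normal() * resid[m][1])
            for p in dag.parents(m):
                val += dag.coefficient(p, m) * (z[p] if p in z else z_all.get(p, 0.0))
            z[m] = val
        dates = {m: mu[m] + scale[m] * z[m] for m in MILESTONES}
        if _gaps_ok(dates):
            return dates, z, exo_year
    # clamp: enforce the departure floor and minimum gaps forward
    dates["depart_breeding"] = max(dates["depart_breeding"], 1.0)
    for (a, b), g in MIN_GAPS.items():
        if dates[b] - dates[a] < g:
            dates[b] = dates[a] + g
    return dates, z, exo_year


def _gaps_ok(dates) -> bool:
    # breeding departure cannot precede the cycle start by construction of
    # cycle time; 1-day floor keeps the rendered itinerary feasible
    if dates["depart_breeding"] < 1.0:
        return False
    return all(dates[b] - dates[a] >= g for (a, b), g in MIN_GAPS.items())


def simulate_mortality_z(z: dict, config: SimConfig,
                         rng: np.random.Generator) -> str | None:
    """Sequential stage-wise Bernoulli mortality on standardized timing."""
    if not config.mortality_enabled:
        return None
    for m in MILESTONES:
        a, s = config.mortality_logit.get(m, (-50.0, 0.0))
        p = 1.0 / (1.0 + np.exp(-(a + s * z[m])))
        if rng.random() < p:
            return m
    return None


def simulate_mortality(record: TrueRecord, config: SimConfig,
                       rng: np.random.Generator | None = None) -> str | None:
    """Death stage for a record (standalone operation surface)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return simulate_mortality_z(record.z, config, rng)


# ---------------------------------------------------------------------------
# Track rendering
# ---------------------------------------------------------------------------

def _itinerary(record: TrueRecord, config: SimConfig) -> list[tuple]:
    """Stopover waypoints with arrival/departure cycle-times.

    The bird dwells at each waypoint and flies between them along great
    circles at the configured flight speed; flight legs are anchored so
    that the true milestone times are honoured exactly (e.g. the southern
    Sahara edge is crossed at the southbound-crossing date).
    """
    v = config.flight_speed_kmh
    d = record.dates
    br = (record.breeding_lat, record.breeding_lon)
    eu = (record.eu_stopover_lat, -4.5 if record.route == "SW" else 12.8)
    sahel = (12.0, -5.0 if record.route == "SW" else 8.0)
    winter = record.waypoints.get("winter", (-2.0, 20.0))
    wa = (9.5, record.wa_stopover_lon)
    staging = (46.0, -1.0)

    def flight_days(a, b):
        dist = haversine_km(a[0], a[1], b[0], b[1])
        if dist > 0 and v <= 0:
            raise ValueError("zero flight speed with distinct waypoints")
        return dist / v / HOURS_PER_DAY

    m1 = d["depart_breeding"]
    t_eu_arr = m1 + flight_days(br, eu)
    # southbound trans-Sahara leg: cross the southern Sahara edge (16 N)
    # exactly at the crossing date
    frac = _crossing_fraction(eu, sahel, 16.0)
    t_leg = flight_days(eu, sahel)
    t_eu_dep = d["complete_sahara_south"] - frac * t_leg
    t_sahel_arr = d["complete_sahara_south"] + (1.0 - frac) * t_leg
    t_sahel_dep = d["arrive_winter"] - flight_days(sahel, winter)
    t_wa_arr = d["depart_winter"] + flight_days(winter, wa)
    t_staging_arr = d["depart_west_africa"] + flight_days(wa, staging)
    t_staging_dep = d["arrive_breeding"] - flight_days(staging, br)
    its = [
        (br, 0.0, m1),
        (eu, t_eu_arr, t_eu_dep),
        (sahel, t_sahel_arr, t_sahel_dep),
        (winter, d["arrive_winter"], d["depart_winter"]),
        (wa, t_wa_arr, d["depart_west_africa"]),
        (staging, t_staging_arr, t_staging_dep),
        (br, d["arrive_breeding"], max(365.0, d["arrive_breeding"] + 3.0)),
    ]
    for (pt, a, dep) in its:
        if dep < a - 1e-9:
            raise ValueError(
                f"infeasible itinerary for {record.bird_id} year {record.year}: "
                f"arrive {a:.2f} after depart {dep:.2f} at {pt}")
    return its


def _crossing_fraction(a, b, lat_edge: float) -> float:
    pts = great_circle_points(a[0], a[1], b[0], b[1], n=200)
    below = np.flatnonzero(pts[:, 0] < lat_edge)
    if len(below) == 0 or below[0] == 0:
        return 0.0
    i = below[0]
    lat0, lat1 = pts[i - 1, 0], pts[i, 0]
    sub = (lat0 - lat_edge) / (lat0 - lat1) if lat0 != lat1 else 0.0
    return ((i - 1) + sub) / (len(pts) - 1)


def _position_at(its: list[tuple], t: float) -> tuple[float, float]:
    for j, (pt, a, dep) in enumerate(its):
        if a <= t <= dep:
            return pt
        if t < a:
            prev_pt, _, prev_dep = its[j - 1]
            frac = (t - prev_dep) / (a - prev_dep) if a > prev_dep else 1.0
            return great_circle_interpolate(prev_pt[0], prev_pt[1],
                                            pt[0], pt[1], frac)
    return its[-1][0]


def render_track(record: TrueRecord, config: SimConfig,
                 rng: np.random.Generator | None = None,
                 t_start: float = 0.0) -> pd.DataFrame:
    """Duty-cycled, noisy fix table for one bird-year.

    Fixes are emitted only inside on-windows of the duty cycle; whole
    cycles are dropped with probability ``p_missed_cycle``; positions get
    isotropic Gaussian noise with SD ``fix_noise_km``; the track is
    truncated at the death time if any.  ``t_start`` delays emission (used
    when the previous cycle's breeding arrival spills past the year
    boundary, so a bird is never reported at the breeding grounds before
    it has arrived).
    """
    rng = rng if rng is not None else np.random.default_rng(
        (config.seed, zlib.crc32(record.bird_id.encode()), record.year))
    its = _itinerary(record, config)
    if record.death_time is None:
        end = max(365.0, record.dates["arrive_breeding"] + 3.0)
    else:
        end = record.death_time
    cycle_days = config.cycle_length_hours / HOURS_PER_DAY
    on_days = config.duty_on_hours / HOURS_PER_DAY
    if config.fixes_per_window == 1:
        offsets = np.array([config.duty_on_hours / 2.0]) / HOURS_PER_DAY
    else:
        offsets = np.linspace(0.5, config.duty_on_hours - 2.0,
                              config.fixes_per_window) / HOURS_PER_DAY
    # the tag's duty schedule runs continuously in wall time, so the
    # window grid is anchored per bird, not per year
    anchor = config.cycle_anchor(record.year)
    year_offset = (anchor - config.cycle_anchor(0)) / pd.Timedelta(days=1)
    phase_rng = np.random.default_rng(
        (config.seed, 424242, zlib.crc32(record.bird_id.encode())))
    phase = float(phase_rng.uniform(0, cycle_days))
    rows = []
    k = int(np.floor((year_offset + t_start - phase) / cycle_days))
    while True:
        w0 = phase + k * cycle_days - year_offset  # cycle time of this year
        k += 1
        if w0 > end:
            break
        if rng.random() < config.p_missed_cycle:
            continue
        for off in offsets:
            t = w0 + off
            if t <= t_start or t > end or t > w0 + on_days:
                continue
            lat, lon = _position_at(its, t)
            if config.fix_noise_km > 0:
                lat, lon = destination_offset_km(
                    lat, lon,
                    float(rng.standard_normal() * config.fix_noise_km),
                    float(rng.standard_normal() * config.fix_noise_km))
            rows.append((record.bird_id, anchor + pd.Timedelta(days=t),
                         lat, lon, "3"))
    df = pd.DataFrame(rows, columns=["bird_id", "t", "lat", "lon", "lc"])
    if len(df):
        df["t"] = pd.to_datetime(df["t"], utc=True)
    return df


def render_population(records: list[TrueRecord],
                      config: SimConfig) -> pd.DataFrame:
    """Fix table for a whole simulated population (sorted by bird, time)."""
    rng = np.random.default_rng((config.seed, 7_777_777))
    prev_end: dict[str, pd.Timestamp] = {}
    frames = []
    for r in sorted(records, key=lambda x: (x.bird_id, x.year)):
        anchor = config.cycle_anchor(r.year)
        t_start = 0.0
        if r.bird_id in prev_end:
            t_start = max(0.0, (prev_end[r.bird_id] - anchor)
                          / pd.Timedelta(days=1))
        frames.append(render_track(r, config, rng, t_start=t_start))
        stop = r.death_time if r.death_time is not None else max(
            365.0, r.dates["arrive_breeding"] + 3.0)
        prev_end[r.bird_id] = anchor + pd.Timedelta(days=stop)
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["bird_id", "t", "lat", "lon", "lc"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["bird_id", "t"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

def metadata_table(records: list[TrueRecord]) -> pd.DataFrame:
    """One row per bird: tagging site, habitat, route, breeding coords."""
    rows = {}
    for r in records:
        rows.setdefault(r.bird_id, dict(
            bird_id=r.bird_id, tagging_site=r.tagging_site, habitat=r.habitat,
            route=r.route, breeding_lat=r.breeding_lat,
            breeding_lon=r.breeding_lon))
    return pd.DataFrame(list(rows.values()))


def truth_milestone_table(records: list[TrueRecord],
                          truncate_at_death: bool = True,
                          start_year: int = 2012) -> pd.DataFrame:
    """Wide bird-year truth table of milestone dates and covariates.

    ``cycle_id`` uses the calendar starting year (``start_year + year``),
    matching the ids the extraction pipeline assigns.
    """
    rows = []
    for r in records:
        dates = r.observed_milestones() if truncate_at_death else dict(r.dates)
        row = dict(bird_id=r.bird_id, year=r.year,
                   cycle_id=f"{r.bird_id}-{start_year + r.year}",
                   habitat=r.habitat, route=r.route,
                   breeding_lat=r.breeding_lat, breeding_lon=r.breeding_lon,
                   eu_stopover_lat=r.eu_stopover_lat,
                   wa_stopover_lon=r.wa_stopover_lon,
                   death_stage=r.death_stage if r.death_stage else "")
        for m in MILESTONES:
            row[m] = dates.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def deaths_table(records: list[TrueRecord],
                 start_year: int = 2012) -> pd.DataFrame:
    """Deaths CSV: bird, last milestone survived, certainty flag."""
    rows = []
    for r in records:
        if r.death_stage is not None:
            rows.append(dict(bird_id=r.bird_id,
                             cycle_id=f"{r.bird_id}-{start_year + r.year}",
                             death_after=r.death_stage, certain=True))
    return pd.DataFrame(rows, columns=["bird_id", "cycle_id", "death_after",
                                       "certain"])


def apply_missingness(table: pd.DataFrame, rate: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Blank each milestone entry independently with the given rate
    (emulating uncertainty-filtered milestones)."""
    out = table.copy()
    for m in MILESTONES:
        mask = rng.random(len(out)) < rate
        out.loc[mask, m] = np.nan
    return out


def noise_free(config: SimConfig) -> SimConfig:
    """The same conditions with positional noise and missed cycles off."""
    return replace(config, fix_noise_km=0.0, p_missed_cycle=0.0)
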