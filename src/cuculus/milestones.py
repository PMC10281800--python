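"""Migratory milestone extraction, uncertainty, filtering and datasets.

Six milestones summarize the staged annual cycle: departure from the
breeding grounds, completion of the southbound Sahara crossing, arrival to
and departure from the wintering grounds, departure from the West African
stopover, and arrival at the breeding grounds.  Each milestone is dated
from a basis fix (or stopover boundary); its uncertainty is the time gap
to the neighbouring fix on the side the definition leaves open, and
milestones with uncertainty above five days are excluded from analysis.

Cycle time is continuous days since 1 June of the cycle's starting year;
the same quantity as Julian day of the event is carried for reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dag import MILESTONES
from .geometry import chord_intersects, haversine_km, is_north_of, is_south_of
from .io import RegionSet

UNCERTAINTY_MAX_DAYS = 5.0
SAHARA_BASIS_UNCERTAINTY_DAYS = 2.0
BREEDING_DISC_KM = 50.0
DEPARTURE_DISTANCE_KM = 100.0
#: cycle-day boundary between the post-breeding (Jun-Dec) and pre-breeding
#: (Jan-Jun) halves of the cycle; day 214 after 1 June is 1 January.
PRE_BREEDING_START_DAY = 214.0

DEPARTURE_KINDS = {"depart_breeding", "depart_winter", "depart_west_africa"}
ARRIVAL_KINDS = {"complete_sahara_south", "arrive_winter", "arrive_breeding"}


def cycle_start_year(t: pd.Timestamp) -> int:
    return t.year if (t.month, t.day) >= (6, 1) else t.year - 1


def cycle_days(t: pd.Timestamp, start_year: int) -> float:
    anchor = pd.Timestamp(year=start_year, month=6, day=1, tz="UTC")
    return (t - anchor) / pd.Timedelta(days=1)


def extract_milestones(stopovers: pd.DataFrame, fixes: pd.DataFrame,
                       regions: RegionSet, meta: pd.DataFrame,
                       breeding_disc_km: float = BREEDING_DISC_KM,
                       enforce_monotone: bool = True) -> pd.DataFrame:
    """Derive all six milestones for every bird and migratory cycle.

    ``meta`` must carry ``bird_id``, ``breeding_lat``, ``breeding_lon``.
    A bird with no qualifying fixes for some milestone simply lacks that
    milestone (not an error).
    """
    for name in ("sahara", "wintering_grounds", "west_africa", "breeding_area"):
        regions[name]  # raises if missing
    meta_idx = meta.set_index("bird_id")
    rows = []
    for bird, bf in fixes.groupby("bird_id", sort=True):
        if bird not in meta_idx.index:
            continue
        b_lat = float(meta_idx.loc[bird, "breeding_lat"])
        b_lon = float(meta_idx.loc[bird, "breeding_lon"])
        bst = stopovers[stopovers["bird_id"] == bird]
        bf = bf.sort_values("t").reset_index(drop=True)
        years = sorted({cycle_start_year(t) for t in bf["t"]})
        for year in years:
            anchor = pd.Timestamp(year=year, month=6, day=1, tz="UTC")
            # a cycle's events may spill a few days past the nominal year
            # boundary (late spring arrivals), so the window is 376 days
            cyc_end = anchor + pd.Timedelta(days=376)
            cyc_fixes = bf[(bf["t"] >= anchor) & (bf["t"] < cyc_end)]
            if len(cyc_fixes) == 0:
                continue
            cyc_stops = bst[(bst["start"] < cyc_end)
                            & (bst["end"] > anchor)] if len(bst) else bst
            found = _extract_cycle(cyc_stops, cyc_fixes, regions,
                                   b_lat, b_lon, year, breeding_disc_km)
            for kind, (t_event, basis_t) in found.items():
                rows.append(dict(
                    bird_id=bird, cycle_id=f"{bird}-{year}", kind=kind,
                    t=t_event, basis_t=basis_t,
                    date_cycle_days=cycle_days(t_event, year),
                    julian_day=float(t_event.dayofyear)
                    + t_event.hour / 24.0))
    out = pd.DataFrame(rows, columns=["bird_id", "cycle_id", "kind", "t",
                                      "basis_t", "date_cycle_days",
                                      "julian_day"])
    if len(out) == 0:
        return out
    out["uncertainty_days"] = [
        milestone_uncertainty(r, fixes[fixes["bird_id"] == r["bird_id"]],
                              regions)
        for _, r in out.iterrows()]
    if enforce_monotone:
        out = _drop_non_monotone(out)
    return out.reset_index(drop=True)


def _extract_cycle(stops, cyc_fixes, regions, b_lat, b_lon, year,
                   breeding_disc_km) -> dict:
    """Milestone event and basis-fix times for one bird-cycle."""
    sahara = regions["sahara"]
    winter = regions["wintering_grounds"]
    wafrica = regions["west_africa"]
    found: dict[str, tuple] = {}
    t0 = pd.Timestamp(year=year, month=6, day=1, tz="UTC")
    day = (cyc_fixes["t"] - t0) / pd.Timedelta(days=1)
    south_half = cyc_fixes[day < PRE_BREEDING_START_DAY]
    north_half = cyc_fixes[day >= PRE_BREEDING_START_DAY]

    # M1: end of the last breeding-disc stopover before the first fix
    # more than 100 km south of the breeding site.  Only fixes after the
    # bird has been seen at the breeding site this cycle count as
    # departure evidence (the cycle may open with the tail of the previous
    # spring's arrival flight).
    dist_b = np.atleast_1d(haversine_km(cyc_fixes["lat"].to_numpy(),
                                        cyc_fixes["lon"].to_numpy(),
                                        b_lat, b_lon))
    at_home = cyc_fixes[dist_b <= breeding_disc_km]
    departed = cyc_fixes[(dist_b > DEPARTURE_DISTANCE_KM)
                         & (cyc_fixes["lat"] < b_lat)]
    if len(at_home):
        departed = departed[departed["t"] > at_home["t"].iloc[0]]
    if len(departed) and len(stops) and len(at_home):
        t_dep = departed["t"].iloc[0]
        near = stops[
            (haversine_km(stops["lat"].to_numpy(), stops["lon"].to_numpy(),
                          b_lat, b_lon) <= breeding_disc_km)
            & (stops["end"] < t_dep)]
        if len(near):
            s = near.iloc[-1]
            found["depart_breeding"] = (s["end"], _member_end_time(s, cyc_fixes))

    # M2: first fix south of the Sahara after a northern-side fix, southbound.
    seen_north = False
    for _, f in south_half.iterrows():
        south = is_south_of(sahara, f["lat"], f["lon"])
        if south and seen_north:
            found["complete_sahara_south"] = (f["t"], f["t"])
            break
        if not south:
            seen_north = True

    # M3/M4: first/last stopover inside the wintering grounds.
    if len(stops):
        in_winter = stops[[_covers(winter, la, lo)
                           for la, lo in zip(stops["lat"], stops["lon"])]]
        if len(in_winter):
            s3 = in_winter.iloc[0]
            found["arrive_winter"] = (s3["start"], s3["start"])
            s4 = in_winter.iloc[-1]
            # departure requires evidence the bird actually moved on: a
            # later fix away from the stopover (a tag dying on site must
            # not fabricate a departure)
            after = cyc_fixes[cyc_fixes["t"] > s4["end"]]
            if len(after):
                d_after = np.atleast_1d(haversine_km(
                    after["lat"].to_numpy(), after["lon"].to_numpy(),
                    float(s4["lat"]), float(s4["lon"])))
                if (d_after > 50.0).any():
                    found["depart_winter"] = (s4["end"],
                                              _member_end_time(s4, cyc_fixes))

    # M5: end of the last West African stopover before a northbound
    # Sahara-interior or trans-Sahara fix.
    t_n = None
    was_south = False
    for _, f in north_half.iterrows():
        in_sahara = _covers(sahara, f["lat"], f["lon"])
        north = is_north_of(sahara, f["lat"], f["lon"])
        if in_sahara or (north and was_south):
            t_n = f["t"]
            break
        if is_south_of(sahara, f["lat"], f["lon"]):
            was_south = True
    if t_n is not None:
        if len(stops):
            in_wa = stops[[_covers(wafrica, la, lo)
                           for la, lo in zip(stops["lat"], stops["lon"])]]
            in_wa = in_wa[in_wa["end"] <= t_n]
            # only the northbound staging counts: the autumn Sahel stopover
            # sits in the same region but precedes the wintering period
            if "depart_winter" in found:
                in_wa = in_wa[in_wa["end"] >= found["depart_winter"][0]]
            else:
                spring = t0 + pd.Timedelta(days=PRE_BREEDING_START_DAY)
                in_wa = in_wa[in_wa["end"] >= spring]
        else:
            in_wa = stops
        if len(in_wa):
            s5 = in_wa.iloc[-1]
            found["depart_west_africa"] = (s5["end"],
                                           _member_end_time(s5, cyc_fixes))
        else:
            before = cyc_fixes[cyc_fixes["t"] < t_n]
            if len(before):
                f5 = before.iloc[-1]
                found["depart_west_africa"] = (f5["t"], f5["t"])

    # M6: first spring fix within the breeding disc.
    if len(north_half):
        dist6 = haversine_km(north_half["lat"].to_numpy(),
                             north_half["lon"].to_numpy(), b_lat, b_lon)
        back = north_half[np.atleast_1d(dist6) <= breeding_disc_km]
        if len(back):
            found["arrive_breeding"] = (back["t"].iloc[0], back["t"].iloc[0])
    return found


def _covers(polygon, lat, lon) -> bool:
    from .geometry import point_in_polygon
    return point_in_polygon(polygon, float(lat), float(lon))


def _member_end_time(stopover: pd.Series, cyc_fixes: pd.DataFrame):
    """Last real fix at or before the (possibly gap-extended) stopover end."""
    before = cyc_fixes[cyc_fixes["t"] <= stopover["end"]]
    return before["t"].iloc[-1] if len(before) else stopover["end"]


def milestone_uncertainty(milestone: pd.Series, bird_fixes: pd.DataFrame,
                          regions: RegionSet) -> float:
    """Gap (days) between the basis fix and the neighbouring fix.

    Departure-type milestones look to the NEXT fix, arrival-type to the
    PREVIOUS.  When West-Africa departure is based on a fix inside the
    Sahara, the uncertainty is exactly two days (the desert crossing is
    short).
    """
    basis_t = milestone["basis_t"]
    if pd.isna(basis_t):
        raise ValueError("milestone has no basis fix")
    kind = milestone["kind"]
    ts = bird_fixes["t"].sort_values().reset_index(drop=True)
    if kind == "depart_west_africa":
        at_basis = bird_fixes[bird_fixes["t"] == basis_t]
        if len(at_basis):
            f = at_basis.iloc[0]
            if _covers(regions["sahara"], f["lat"], f["lon"]):
                return SAHARA_BASIS_UNCERTAINTY_DAYS
    if kind in DEPARTURE_KINDS:
        later = ts[ts > basis_t]
        if len(later) == 0:
            return np.inf
        return float((later.iloc[0] - basis_t) / pd.Timedelta(days=1))
    earlier = ts[ts < basis_t]
    if len(earlier) == 0:
        return np.inf
    return float((basis_t - earlier.iloc[-1]) / pd.Timedelta(days=1))


def filter_uncertain(milestones: pd.DataFrame,
                     threshold: float = UNCERTAINTY_MAX_DAYS) -> pd.DataFrame:
    """Exclude milestones with uncertainty strictly above the threshold."""
    out = milestones.copy()
    out["retained_flag"] = out["uncertainty_days"] <= threshold
    return out[out["retained_flag"]].reset_index(drop=True)


def _drop_non_monotone(milestones: pd.DataFrame) -> pd.DataFrame:
    """Keep per cycle the longest subsequence whose kind order agrees with
    date order (classic longest-increasing-subsequence, so a single
    misdated milestone cannot evict several consistent ones)."""
    keep = []
    order = {k: i for i, k in enumerate(MILESTONES)}
    for _, grp in milestones.groupby("cycle_id", sort=False):
        g = grp.sort_values("date_cycle_days")
        ranks = [order[k] for k in g["kind"]]
        n = len(ranks)
        best_len = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if ranks[j] < ranks[i] and best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
        i = int(np.argmax(best_len))
        chosen = []
        while i >= 0:
            chosen.append(i)
            i = prev[i]
        keep.extend(g.index[i] for i in chosen)
    return milestones.loc[sorted(keep)]


def classify_route(southbound_best_fixes: pd.DataFrame, regions: RegionSet,
                   previous_year_route: str | None = None) -> str:
    """SW if the bird transits Iberia, SE if Italy, judged on best fixes and
    the great-circle chords linking them; otherwise inherit last year's
    route, else 'unclassified'."""
    iberia = regions["iberia"]
    italy = regions["italy"]
    fx = southbound_best_fixes.sort_values("t")
    for _, f in fx.iterrows():
        if _covers(iberia, f["lat"], f["lon"]):
            return "SW"
        if _covers(italy, f["lat"], f["lon"]):
            return "SE"
    pts = fx[["lat", "lon"]].to_numpy()
    for a, b in zip(pts[:-1], pts[1:]):
        if chord_intersects(iberia, a[0], a[1], b[0], b[1]):
            return "SW"
        if chord_intersects(italy, a[0], a[1], b[0], b[1]):
            return "SE"
    if previous_year_route in ("SW", "SE"):
        return previous_year_route
    return "unclassified"


def within_individual_anomaly(milestones: pd.DataFrame) -> pd.DataFrame:
    """Date minus the bird's across-year mean date for the same milestone.

    Only bird-kind groups present in more than one year (the repeat
    dataset) are returned; anomalies sum to zero within each group.
    """
    rep = build_datasets(milestones)[1]
    if len(rep) == 0:
        out = rep.copy()
        out["anomaly_days"] = pd.Series([], dtype=float)
        return out
    out = rep.copy()
    out["anomaly_days"] = (
        out["date_cycle_days"]
        - out.groupby(["bird_id", "kind"])["date_cycle_days"].transform("mean"))
    return out


def build_datasets(milestones: pd.DataFrame):
    """(full dataset, repeat dataset) split.

    The repeat dataset keeps only bird-kind groups observed in >= 2 cycles.
    """
    full = milestones.reset_index(drop=True)
    if len(full) == 0:
        return full, full.copy()
    counts = full.groupby(["bird_id", "kind"])["cycle_id"].transform("nunique")
    repeat = full[counts >= 2].reset_index(drop=True)
    return full, repeat


def repeat_group_histogram(repeat: pd.DataFrame) -> pd.Series:
    """How many bird-kind groups contribute 2, 3, ... cycles."""
    if len(repeat) == 0:
        return pd.Series(dtype=int)
    sizes = repeat.groupby(["bird_id", "kind"])["cycle_id"].nunique()
    return sizes.value_counts().sort_index()


def stopover_covariates(stopovers: pd.DataFrame, milestones: pd.DataFrame,
                        regions: RegionSet) -> pd.DataFrame:
    """Per-cycle stopover-location covariates for the timing model.

    ``eu_stopover_lat``: latitude of the last European stopover before the
    southbound Sahara crossing; ``wa_stopover_lon``: longitude of the last
    West African stopover before the northbound crossing (the stopover that
    defines West-Africa departure).
    """
    wafrica = regions["west_africa"]
    milestones = milestones.copy()
    if "t" not in milestones.columns:
        # reconstruct event timestamps from cycle time (CSV round trip)
        milestones["t"] = [
            pd.Timestamp(year=int(c.rsplit("-", 1)[1]), month=6, day=1,
                         tz="UTC") + pd.Timedelta(days=float(d))
            for c, d in zip(milestones["cycle_id"],
                            milestones["date_cycle_days"])]
    rows = []
    for cyc, grp in milestones.groupby("cycle_id"):
        bird = grp["bird_id"].iloc[0]
        ss = stopovers[stopovers["bird_id"] == bird]
        eu_lat = np.nan
        wa_lon = np.nan
        m2 = grp[grp["kind"] == "complete_sahara_south"]
        if len(m2) and len(ss):
            before = ss[(ss["end"] <= m2["t"].iloc[0]) & (ss["lat"] > 31.0)]
            if len(before):
                eu_lat = float(before["lat"].iloc[-1])
        m5 = grp[grp["kind"] == "depart_west_africa"]
        if len(m5) and len(ss):
            wa = ss[[_covers(wafrica, la, lo)
                     for la, lo in zip(ss["lat"], ss["lon"])]]
            wa = wa[wa["end"] <= m5["t"].iloc[0] + pd.Timedelta(days=1)]
            if len(wa):
                wa_lon = float(wa["lon"].iloc[-1])
        rows.append(dict(cycle_id=cyc, eu_stopover_lat=eu_lat,
                         wa_stopover_lon=wa_lon))
    return pd.DataFrame(rows, columns=["cycle_id", "eu_stopover_lat",
                                       "wa_stopover_lon"])


def milestone_wide_table(milestones: pd.DataFrame,
                         meta: pd.DataFrame,
                         value: str = "date_cycle_days") -> pd.DataFrame:
    """Pivot the long milestone table to one row per cycle with covariates,
    ready for the path models (missing milestones become NaN)."""
    wide = milestones.pivot_table(index=["bird_id", "cycle_id"],
                                  columns="kind", values=value,
                                  aggfunc="first").reset_index()
    wide.columns.name = None
    for m in MILESTONES:
        if m not in wide.columns:
            wide[m] = np.nan
    return wide.merge(meta, on="bird_id", how="left")
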