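"""Track segmentation: transmission cycles, best locations, stopovers.

The rules implemented here follow the tracking protocol of duty-cycled
Argos tags: fixes more than 10 h apart belong to different transmission
cycles; a stopover is a run of two or more consecutive cycles whose best
locations cluster within 50 km, lasting at least one day; and when whole
cycles go missing before the bird is next seen elsewhere, the bird is
assumed to have remained at the stopover until the last missed location
was expected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import haversine_km
from .io import lc_quality

CYCLE_GAP_HOURS = 10.0
STOPOVER_RADIUS_KM = 50.0
MIN_STOPOVER_DAYS = 1.0


def assign_cycles(fixes: pd.DataFrame,
                  gap_hours: float = CYCLE_GAP_HOURS) -> pd.DataFrame:
    """Partition each bird's time-sorted fixes into transmission cycles.

    A new cycle starts exactly when the gap to the previous fix exceeds
    ``gap_hours``.  Returns a copy with a ``cycle_index`` column.
    """
    out = fixes.sort_values(["bird_id", "t"]).reset_index(drop=True).copy()
    if len(out) == 0:
        out["cycle_index"] = pd.Series([], dtype=int)
        return out
    gap = out.groupby("bird_id")["t"].diff().dt.total_seconds() / 3600.0
    new_cycle = gap.isna() | (gap > gap_hours)
    out["cycle_index"] = new_cycle.groupby(out["bird_id"]).cumsum().astype(int) - 1
    return out


def best_of_cycle(cycle: pd.DataFrame) -> pd.Series:
    """Best fix of one cycle: highest Argos quality class, ties broken by
    distance to the cycle's coordinate-wise median, then by earliest time."""
    if len(cycle) == 0:
        raise ValueError("empty transmission cycle")
    q = cycle["lc"].map(lc_quality)
    best_q = cycle[q == q.max()]
    med_lat = best_q["lat"].median()
    med_lon = best_q["lon"].median()
    d = haversine_km(best_q["lat"].to_numpy(), best_q["lon"].to_numpy(),
                     med_lat, med_lon)
    d = np.atleast_1d(d)
    cand = best_q.iloc[np.flatnonzero(d == d.min())]
    return cand.sort_values("t").iloc[0]


def best_fix_table(fixes_with_cycles: pd.DataFrame) -> pd.DataFrame:
    """One best fix per (bird, cycle), with the cycle's time span."""
    rows = []
    for (bird, ci), grp in fixes_with_cycles.groupby(["bird_id", "cycle_index"],
                                                     sort=True):
        b = best_of_cycle(grp)
        rows.append(dict(bird_id=bird, cycle_index=int(ci), t=b["t"],
                         lat=float(b["lat"]), lon=float(b["lon"]),
                         lc=b["lc"], t_first=grp["t"].min(),
                         t_last=grp["t"].max(), n_fixes=len(grp)))
    cols = ["bird_id", "cycle_index", "t", "lat", "lon", "lc", "t_first",
            "t_last", "n_fixes"]
    return pd.DataFrame(rows, columns=cols)


def detect_stopovers(best_fixes: pd.DataFrame,
                     radius_km: float = STOPOVER_RADIUS_KM,
                     min_days: float = MIN_STOPOVER_DAYS) -> pd.DataFrame:
    """Greedy left-to-right chaining of consecutive cycles into stopovers.

    A cycle joins the open stopover when its best fix lies within
    ``radius_km`` (inclusive) of the running centroid; the stopover closes
    when a cycle fails the test and is emitted only with >= 2 member
    cycles and a first-to-last span of at least ``min_days``.
    """
    stopovers = []
    for bird, grp in best_fixes.groupby("bird_id", sort=True):
        grp = grp.sort_values("cycle_index")
        members: list[pd.Series] = []
        for _, row in grp.iterrows():
            if members:
                c_lat = np.mean([m["lat"] for m in members])
                c_lon = np.mean([m["lon"] for m in members])
                if haversine_km(row["lat"], row["lon"], c_lat, c_lon) <= radius_km:
                    members.append(row)
                    continue
                _emit(stopovers, bird, members, min_days)
            members = [row]
        _emit(stopovers, bird, members, min_days)
    cols = ["bird_id", "start", "end", "lat", "lon", "n_cycles",
            "first_cycle", "last_cycle", "gap_extended"]
    df = pd.DataFrame(stopovers, columns=cols)
    return df.reset_index(drop=True)


def _emit(acc: list, bird: str, members: list, min_days: float) -> None:
    if len(members) < 2:
        return
    start, end = members[0]["t"], members[-1]["t"]
    if (end - start) < pd.Timedelta(days=min_days):
        return
    acc.append(dict(
        bird_id=bird, start=start, end=end,
        lat=float(np.mean([m["lat"] for m in members])),
        lon=float(np.mean([m["lon"] for m in members])),
        n_cycles=len(members),
        first_cycle=int(members[0]["cycle_index"]),
        last_cycle=int(members[-1]["cycle_index"]),
        gap_extended=False))


def extend_through_gaps(stopovers: pd.DataFrame, best_fixes: pd.DataFrame,
                        duty_on_hours: float = 10.0,
                        duty_off_hours: float = 48.0,
                        radius_km: float = STOPOVER_RADIUS_KM) -> pd.DataFrame:
    """Push stopover ends through missed transmission cycles.

    When one or more whole cycles are missing between a stopover's last
    member cycle and the next observed location, and that next location is
    demonstrably elsewhere (> ``radius_km`` from the centroid), the end is
    moved to the expected on-window time of the last missed cycle, anchored
    on the last received cycle.  Missing cycles before a same-place fix
    need no handling here: the chaining rule already bridges them.
    """
    period = pd.Timedelta(hours=duty_on_hours + duty_off_hours)
    if period <= pd.Timedelta(0):
        raise ValueError("duty schedule inconsistency: non-positive period")
    out = stopovers.copy()
    for i, s in out.iterrows():
        nxt = best_fixes[(best_fixes["bird_id"] == s["bird_id"])
                         & (best_fixes["cycle_index"] > s["last_cycle"])]
        if len(nxt) == 0:
            continue
        nrow = nxt.iloc[0]
        if haversine_km(nrow["lat"], nrow["lon"], s["lat"], s["lon"]) <= radius_km:
            continue
        gap = nrow["t"] - s["end"]
        if gap < pd.Timedelta(0):
            raise RuntimeError("schedule inconsistency: negative cycle gap")
        n_missed = int(round(gap / period)) - 1
        if n_missed >= 1:
            out.at[i, "end"] = s["end"] + n_missed * period
            out.at[i, "gap_extended"] = True
    return out


def segment(fixes: pd.DataFrame, gap_hours: float = CYCLE_GAP_HOURS,
            radius_km: float = STOPOVER_RADIUS_KM,
            min_days: float = MIN_STOPOVER_DAYS,
            duty_on_hours: float = 10.0, duty_off_hours: float = 48.0,
            extend_gaps: bool = True):
    """Full segmentation of a fix table.

    Returns ``(fixes_with_cycles, best_fixes, stopovers)``.
    """
    cyc = assign_cycles(fixes, gap_hours=gap_hours)
    best = best_fix_table(cyc)
    stops = detect_stopovers(best, radius_km=radius_km, min_days=min_days)
    if extend_gaps and len(stops):
        stops = extend_through_gaps(stops, best, duty_on_hours=duty_on_hours,
                                    duty_off_hours=duty_off_hours,
                                    radius_km=radius_km)
    return cyc, best, stops
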