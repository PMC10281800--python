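"""Reading and writing the external formats the pipeline touches.

Fixes travel as Movebank-dialect CSV; geographic regions as GeoJSON
(RFC 7946) FeatureCollections; stopovers and milestones as flat CSV; model
fits as JSON.  In memory a stream of fixes is a pandas DataFrame with
columns ``bird_id``, ``t`` (timezone-aware UTC), ``lat``, ``lon``, ``lc``
sorted by (bird, time) — the canonical "fix table".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from .geometry import point_in_polygon

MOVEBANK_COLUMNS = {
    "bird_id": "individual-local-identifier",
    "t": "timestamp",
    "lat": "location-lat",
    "lon": "location-long",
    "lc": "argos-lc",
}

#: Argos location-class ranking, best first.  The exact "best location"
#: filtering of the original tagging programme is not public; this
#: configurable ranking is a declared stand-in.
DEFAULT_LC_RANK = ["3", "2", "1", "0", "A", "B", "Z"]

REQUIRED_REGION_NAMES = frozenset(
    ["sahara", "wintering_grounds", "west_africa", "iberia", "italy",
     "breeding_area"]
)


class FixParseError(ValueError):
    """Raised when a fix file has a malformed row or missing column."""


@dataclass
class RegionSet:
    """Named geographic polygons used by milestone extraction."""

    polygons: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self):
        for name, poly in self.polygons.items():
            if not poly.is_valid:
                raise ValueError(f"region {name!r} is not a valid polygon")

    def __getitem__(self, name: str) -> Polygon:
        try:
            return self.polygons[name]
        except KeyError:
            raise KeyError(f"region {name!r} not loaded; have "
                           f"{sorted(self.polygons)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.polygons

    def names(self) -> list[str]:
        return sorted(self.polygons)


def lc_quality(lc, rank=None) -> int:
    """Numeric quality of an Argos class: higher is better; unknown worst."""
    rank = rank if rank is not None else DEFAULT_LC_RANK
    lc = "" if lc is None or (isinstance(lc, float) and np.isnan(lc)) else str(lc)
    try:
        return len(rank) - rank.index(lc)
    except ValueError:
        return 0


def read_fixes(path, dialect: str = "movebank") -> pd.DataFrame:
    """Read a fix CSV into the canonical fix table.

    Rows are sorted by (bird, time); duplicate (bird, timestamp) rows are
    collapsed keeping the best quality class.  Unparseable timestamps are
    reported with their line number.
    """
    if dialect != "movebank":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in MOVEBANK_COLUMNS.values()
               if c != "argos-lc" and c not in raw.columns]
    if missing:
        raise FixParseError(f"missing required column(s): {missing}")
    df = pd.DataFrame({
        "bird_id": raw[MOVEBANK_COLUMNS["bird_id"]].astype(str),
        "lat": pd.to_numeric(raw[MOVEBANK_COLUMNS["lat"]], errors="coerce"),
        "lon": pd.to_numeric(raw[MOVEBANK_COLUMNS["lon"]], errors="coerce"),
        "lc": raw.get(MOVEBANK_COLUMNS["lc"], pd.Series([""] * len(raw))),
    })
    t = pd.to_datetime(raw[MOVEBANK_COLUMNS["t"]], utc=True, errors="coerce",
                       format="mixed")
    bad = t.isna() & raw[MOVEBANK_COLUMNS["t"]].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header = line 1
        raise FixParseError(f"unparseable timestamp at line {line}: "
                            f"{raw[MOVEBANK_COLUMNS['t']][bad].iloc[0]!r}")
    df["t"] = t
    df["lc"] = df["lc"].fillna("")
    if not (df["lat"].dropna().between(-90, 90).all()
            and df["lon"].dropna().between(-180, 180).all()):
        raise FixParseError("coordinates outside WGS84 bounds")
    df = df.dropna(subset=["t", "lat", "lon"])
    df["quality"] = df["lc"].map(lc_quality)
    df = (df.sort_values(["bird_id", "t", "quality"],
                         ascending=[True, True, False])
            .drop_duplicates(subset=["bird_id", "t"], keep="first")
            .drop(columns="quality")
            .reset_index(drop=True))
    return df[["bird_id", "t", "lat", "lon", "lc"]]


def write_fixes(df: pd.DataFrame, path) -> None:
    """Write a fix table as Movebank-dialect CSV (6 d.p. degrees, 1 s time)."""
    out = pd.DataFrame({
        MOVEBANK_COLUMNS["bird_id"]: df["bird_id"],
        MOVEBANK_COLUMNS["t"]: df["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
        MOVEBANK_COLUMNS["lat"]: df["lat"].round(6),
        MOVEBANK_COLUMNS["lon"]: df["lon"].round(6),
        MOVEBANK_COLUMNS["lc"]: df["lc"],
    })
    out.to_csv(path, index=False)


def read_regions(path=None) -> RegionSet:
    """Load named region polygons from a GeoJSON FeatureCollection.

    With no path, the packaged simplified region set is used.
    """
    if path is None:
        with resources.files("cuculus.data").joinpath("regions.geojson").open() as fh:
            doc = json.load(fh)
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"regions file not found: {path}")
        doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError("regions file must be a GeoJSON FeatureCollection")
    polygons: dict[str, Polygon] = {}
    for feat in doc["features"]:
        name = (feat.get("properties") or {}).get("name")
        if not name:
            raise ValueError("every region feature needs a 'name' property")
        if name in polygons:
            raise ValueError(f"duplicate region name {name!r}")
        polygons[name] = shape(feat["geometry"])
    return RegionSet(polygons)


def point_in_region(regions: RegionSet, name: str, lat: float, lon: float) -> bool:
    """Boundary-inclusive point-in-polygon test for a named region."""
    return point_in_polygon(regions[name], lat, lon)


def write_stopovers(stopovers: pd.DataFrame, path) -> None:
    cols = ["bird_id", "start", "end", "lat", "lon", "n_cycles", "gap_extended"]
    out = stopovers[cols].copy()
    for c in ("start", "end"):
        out[c] = pd.to_datetime(out[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out["lat"] = out["lat"].round(6)
    out["lon"] = out["lon"].round(6)
    out.to_csv(path, index=False)


def read_stopovers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c], utc=True)
    return df


def write_milestones(milestones: pd.DataFrame, path) -> None:
    cols = ["bird_id", "cycle_id", "kind", "date_cycle_days", "julian_day",
            "uncertainty_days", "retained_flag"]
    milestones[cols].to_csv(path, index=False, float_format="%.6f")


def read_milestones(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
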