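"""Geodesic helpers on WGS84 lon/lat.

All distances are great-circle (haversine) with a spherical mean Earth
radius of 6371.0088 km; no projected CRS is used anywhere in the
pipeline.  Polygon containment is boundary-inclusive.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Point, Polygon

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0  # ~111.195 km


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points (or arrays) in degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def point_in_polygon(polygon: Polygon, lat: float, lon: float) -> bool:
    """Boundary-inclusive containment test (closed polygons)."""
    return bool(polygon.covers(Point(lon, lat)))


def great_circle_points(lat1, lon1, lat2, lon2, n: int = 32) -> np.ndarray:
    """``n`` points interpolated along the great circle, as (lat, lon) rows.

    Uses spherical linear interpolation of the unit vectors, so the chord
    follows the geodesic rather than a straight line in lon/lat space.
    """
    v1 = _unit_vector(lat1, lon1)
    v2 = _unit_vector(lat2, lon2)
    omega = math.acos(float(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    ts = np.linspace(0.0, 1.0, n)
    if omega < 1e-12:
        pts = np.outer(np.ones(n), v1)
    else:
        s = math.sin(omega)
        pts = (np.outer(np.sin((1 - ts) * omega), v1) + np.outer(np.sin(ts * omega), v2)) / s
    lats = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lons = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.column_stack([lats, lons])


def great_circle_interpolate(lat1, lon1, lat2, lon2, frac: float) -> tuple[float, float]:
    """Single point a fraction ``frac`` of the way along the geodesic."""
    pts = great_circle_points(lat1, lon1, lat2, lon2, n=3)
    v1 = _unit_vector(lat1, lon1)
    v2 = _unit_vector(lat2, lon2)
    omega = math.acos(float(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    if omega < 1e-12:
        return float(lat1), float(lon1)
    s = math.sin(omega)
    p = (math.sin((1 - frac) * omega) * v1 + math.sin(frac * omega) * v2) / s
    lat = math.degrees(math.asin(max(-1.0, min(1.0, p[2]))))
    lon = math.degrees(math.atan2(p[1], p[0]))
    return lat, lon


def chord_intersects(polygon: Polygon, lat1, lon1, lat2, lon2, n: int = 64) -> bool:
    """Does the great-circle chord between two fixes touch the polygon?

    The geodesic is densified into ``n`` vertices; at the continental scale
    of migration legs this is well inside the 50-km decision tolerances.
    """
    pts = great_circle_points(lat1, lon1, lat2, lon2, n=n)
    line = LineString(np.column_stack([pts[:, 1], pts[:, 0]]))
    return bool(polygon.intersects(line))


def latitude_of_southern_edge(polygon: Polygon, lon: float) -> float:
    """Southernmost latitude of the polygon boundary at a given longitude.

    Used to decide whether a fix lies south of a barrier region (e.g. the
    Sahara) at the longitude actually flown.  Falls back to the polygon's
    overall southern bound when the meridian misses it.
    """
    minx, miny, maxx, maxy = polygon.bounds
    meridian = LineString([(lon, miny - 90.0), (lon, maxy + 90.0)])
    inter = polygon.intersection(meridian)
    if inter.is_empty:
        return float(miny)
    return float(inter.bounds[1])


def is_south_of(polygon: Polygon, lat: float, lon: float) -> bool:
    """True when a point lies strictly south of the region at its longitude."""
    return lat < latitude_of_southern_edge(polygon, lon)


def is_north_of(polygon: Polygon, lat: float, lon: float) -> bool:
    minx, miny, maxx, maxy = polygon.bounds
    meridian = LineString([(lon, miny - 90.0), (lon, maxy + 90.0)])
    inter = polygon.intersection(meridian)
    northern = float(inter.bounds[3]) if not inter.is_empty else float(maxy)
    return lat > northern


def destination_offset_km(lat: float, lon: float, d_north_km: float,
                          d_east_km: float) -> tuple[float, float]:
    """Shift a point by small local north/east offsets in km (flat-earth
    locally; adequate for positional noise of a few km)."""
    new_lat = lat + d_north_km / KM_PER_DEG
    coslat = math.cos(math.radians(lat))
    if abs(coslat) < 1e-9:
        return new_lat, lon
    new_lon = lon + d_east_km / (KM_PER_DEG * coslat)
    return new_lat, new_lon


def _unit_vector(lat, lon) -> np.ndarray:
    latr, lonr = math.radians(lat), math.radians(lon)
    return np.array([math.cos(latr) * math.cos(lonr),
                     math.cos(latr) * math.sin(lonr),
                     math.sin(latr)])
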