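"""Small-scale geographic geometry helpers.

All vector geometry in this package lives in geographic decimal degrees
(lon, lat axis order, as in GeoJSON). Metric questions — "how far is this
point from that boundary?", "how many hectares is this polygon?" — are
answered through a local equirectangular projection: x = R·cos(φ0)·Δλ,
y = R·Δφ about a reference latitude φ0. At the scales this package cares
about (snap tolerances of a few hundred metres, polygons of 10²–10⁶ ha)
the error of this approximation is orders of magnitude below the 20–300 m
positional error already accepted for un-transformed geodetic datums, so
no full geodesic machinery is used.
"""

from __future__ import annotations

import json
import math
from typing import Callable, Iterable

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import nearest_points, transform

EARTH_RADIUS_M = 6_371_000.0
#: great-circle metres per degree of arc on the reference sphere
M_PER_DEG = 2.0 * math.pi * EARTH_RADIUS_M / 360.0


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def local_projector(ref_lat: float, ref_lon: float = 0.0) -> tuple[Callable, Callable]:
    """Return (to_xy, to_lonlat) functions for a local equirectangular frame.

    Both accept and return coordinate pairs in (lon, lat) / (x, y) order so
    they can be fed straight to :func:`shapely.ops.transform`.
    """
    k = M_PER_DEG * math.cos(math.radians(ref_lat))

    def to_xy(lon, lat):
        return (lon - ref_lon) * k, lat * M_PER_DEG

    def to_lonlat(x, y):
        return x / k + ref_lon, y / M_PER_DEG

    return to_xy, to_lonlat


def geom_to_local(geom: BaseGeometry, ref_lat: float, ref_lon: float = 0.0) -> BaseGeometry:
    to_xy, _ = local_projector(ref_lat, ref_lon)
    return transform(to_xy, geom)


def polygon_area_ha(geom: BaseGeometry) -> float:
    """Polygon area in hectares via cosine-of-latitude equal-area scaling.

    The planar degree² area is scaled by cos(latitude of the centroid);
    adequate for threshold logic on landscape-scale polygons.
    """
    c = geom.centroid
    return geom_to_local(geom, c.y, c.x).area / 1.0e4


def distance_to_geom_m(lon: float, lat: float, geom: BaseGeometry) -> float:
    """Metric distance from a point to a geometry (0 if the point touches it)."""
    from shapely.geometry import Point

    to_xy, _ = local_projector(lat, lon)
    return transform(to_xy, geom).distance(Point(to_xy(lon, lat)))


def nearest_point_on(geom: BaseGeometry, lon: float, lat: float) -> tuple[float, float, float]:
    """Nearest point of *geom* to (lon, lat): returns (lon, lat, distance_m)."""
    from shapely.geometry import Point

    to_xy, to_lonlat = local_projector(lat, lon)
    g_xy = transform(to_xy, geom)
    p_xy = Point(to_xy(lon, lat))
    near = nearest_points(g_xy, p_xy)[0]
    nlon, nlat = to_lonlat(near.x, near.y)
    return nlon, nlat, p_xy.distance(near)


def nudge_inside(lon: float, lat: float, snap_lon: float, snap_lat: float,
                 polygon: BaseGeometry, step_deg: float = 1e-6):
    """Move a boundary-snapped point just inside *polygon*.

    The snapped point is advanced ``step_deg`` degrees along the original
    point → boundary direction (which continues into the interior for the
    nearest-boundary point); if the result still does not test inside —
    possible on sharply concave boundaries — the step is escalated and a
    fallback direction toward the polygon's representative point is tried.
    Returns (lon, lat) guaranteed to satisfy ``polygon.covers``.
    """
    from shapely.geometry import Point

    dirs = []
    dx, dy = snap_lon - lon, snap_lat - lat
    n = math.hypot(dx, dy)
    if n > 0:
        dirs.append((dx / n, dy / n))
    rp = polygon.representative_point()
    dx, dy = rp.x - snap_lon, rp.y - snap_lat
    n = math.hypot(dx, dy)
    if n > 0:
        dirs.append((dx / n, dy / n))
    for mult in (1.0, 10.0, 100.0, 1000.0):
        for ux, uy in dirs:
            cand = (snap_lon + ux * step_deg * mult, snap_lat + uy * step_deg * mult)
            if polygon.covers(Point(cand)):
                return cand
    raise ValueError("could not place snapped point inside polygon")


def nudge_outside(lon: float, lat: float, snap_lon: float, snap_lat: float,
                  polygon: BaseGeometry, step_deg: float = 1e-6):
    """Mirror of :func:`nudge_inside`: push a snapped point just outside."""
    from shapely.geometry import Point

    dirs = []
    dx, dy = snap_lon - lon, snap_lat - lat
    n = math.hypot(dx, dy)
    if n > 0:
        dirs.append((dx / n, dy / n))
    rp = polygon.representative_point()
    dx, dy = snap_lon - rp.x, snap_lat - rp.y
    n = math.hypot(dx, dy)
    if n > 0:
        dirs.append((dx / n, dy / n))
    for mult in (1.0, 10.0, 100.0, 1000.0):
        for ux, uy in dirs:
            cand = (snap_lon + ux * step_deg * mult, snap_lat + uy * step_deg * mult)
            if not polygon.covers(Point(cand)):
                return cand
    raise ValueError("could not place snapped point outside polygon")


# ---------------------------------------------------------------------------
# GeoJSON plumbing (RFC 7946: coordinates are [lon, lat])

def read_geojson(path) -> list[tuple[BaseGeometry, dict]]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in doc["features"]]


def write_geojson(path, features: Iterable[tuple[BaseGeometry, dict]]) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": props}
            for g, props in features
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, separators=(",", ":"))
        fh.write("\n")
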