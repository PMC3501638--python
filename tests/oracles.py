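"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) they verify: ray casting instead of prepared-geometry
predicates, the spherical law of cosines instead of the haversine, a
plain group-by instead of the streaming collision filter.
"""

from __future__ import annotations

import math

EARTH_RADIUS_M = 6_371_000.0


def ray_cast_contains(polygon, lon: float, lat: float) -> bool:
    """Even-odd ray casting against a shapely polygon's rings (no shapely
    predicates involved)."""

    def ring_crossings(coords) -> int:
        n = 0
        for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
            if (y1 > lat) != (y2 > lat):
                x_at = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
                if x_at > lon:
                    n += 1
        return n

    crossings = ring_crossings(list(polygon.exterior.coords))
    for hole in polygon.interiors:
        crossings += ring_crossings(list(hole.coords))
    return crossings % 2 == 1


def ray_cast_assign(units, lon: float, lat: float) -> str | None:
    """Containing unit id by exhaustive ray casting (smallest id on ties)."""
    hits = []
    for unit in units:
        polys = ([unit.polygon] if unit.polygon.geom_type == "Polygon"
                 else list(unit.polygon.geoms))
        if any(ray_cast_contains(p, lon, lat) for p in polys):
            hits.append(unit.unit_id)
    return min(hits) if hits else None


def law_of_cosines_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance by the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_M * math.acos(max(-1.0, min(1.0, c)))


def collision_groups(records) -> set[tuple[str, str]]:
    """(accession, source) keys assigned to more than one taxon — plain group-by."""
    seen: dict[tuple[str, str], set] = {}
    for r in records:
        seen.setdefault((r.accession_id, r.source.value), set()).add((r.genus, r.species))
    return {k for k, taxa in seen.items() if len(taxa) > 1}
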