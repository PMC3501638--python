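import math

import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon, box

from museoclim.georef import AdminLevel, AdminUnit, StudyArea
from museoclim.habitat import HabitatMap, VegUnit
from museoclim import geomutil

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def metric_disc(lon, lat, radius_m, quad_segs=16):
    from museoclim.synthgen import _metric_disc

    return _metric_disc(lon, lat, radius_m, quad_segs)


@pytest.fixture
def square_area() -> StudyArea:
    """1°x1° square study area with one small lake and two provinces."""
    boundary = box(25.0, -28.5, 26.0, -27.5)
    lake = metric_disc(25.3, -28.1, 150.0)
    west = box(25.0, -28.5, 25.5, -27.5)
    east = box(25.5, -28.5, 26.0, -27.5)
    return StudyArea(
        boundary=boundary, aquatic=[lake],
        admin_units=[AdminUnit("West Province", AdminLevel.PROVINCE, west),
                     AdminUnit("East Province", AdminLevel.PROVINCE, east)])


@pytest.fixture
def quad_map() -> HabitatMap:
    """Four quadrant units, two bioregions, two biomes; U04 azonal."""
    q = {
        "U01": box(25.0, -28.5, 25.5, -28.0),
        "U02": box(25.5, -28.5, 26.0, -28.0),
        "U03": box(25.0, -28.0, 25.5, -27.5),
        "U04": box(25.5, -28.0, 26.0, -27.5),
    }
    br = {"U01": "SAV-BR1", "U02": "SAV-BR1", "U03": "GRA-BR1", "U04": "GRA-BR1"}
    units = [
        VegUnit(uid, f"Unit {uid}", poly, geomutil.polygon_area_ha(poly), br[uid],
                azonal=(uid == "U04"))
        for uid, poly in q.items()
    ]
    return HabitatMap(
        units=units,
        bioregions={"SAV-BR1": ("Savanna bioregion", "Savanna"),
                    "GRA-BR1": ("Grassland bioregion", "Grassland")},
        biomes={"Savanna": "Savanna", "Grassland": "Grassland", "Azonal": "Azonal"})


@pytest.fixture
def inclusion_map() -> HabitatMap:
    """One large Savanna unit hosting a ~1500 ha Grassland inclusion disc."""
    host_box = box(25.0, -28.5, 26.0, -27.5)
    radius_m = math.sqrt(1500.0 * 1e4 / math.pi)
    disc = metric_disc(25.5, -28.0, radius_m)
    host = host_box.difference(disc)
    units = [
        VegUnit("U01", "Host", host, geomutil.polygon_area_ha(host), "SAV-BR1"),
        VegUnit("U02", "Inclusion", disc, geomutil.polygon_area_ha(disc), "GRA-BR1"),
    ]
    return HabitatMap(
        units=units,
        bioregions={"SAV-BR1": ("Savanna bioregion", "Savanna"),
                    "GRA-BR1": ("Grassland bioregion", "Grassland")},
        biomes={"Savanna": "Savanna", "Grassland": "Grassland", "Azonal": "Azonal"})
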