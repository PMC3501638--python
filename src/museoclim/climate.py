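"""Gridded bioclimatic surfaces and climate-envelope statistics.

Six bioclim-style variables describe each taxon's climatic envelope: mean
annual temperature (MAT), maximum temperature of the warmest month
(MxTWM), minimum temperature of the coldest month (MnTCM), mean annual
precipitation (MAP), and precipitation of the wettest (PWM) and driest
(PDM) months. Surfaces are regular geographic grids read from ESRI ASCII
(.asc) files with a nodata sentinel; temperature layers distributed as
integer tenths of a degree are handled by a ``scale_factor``.

Values at localities can be extracted two ways — direct cell lookup, or a
query against the raster polygonized into discrete-valued polygons — and
the two routes are equivalent by construction, which the test suite
asserts. Per-taxon descriptive statistics are computed under both the
locality and the specimen weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import box
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .georef import GeoPoint


class Variable(str, Enum):
    MAT = "MAT"
    MXTWM = "MxTWM"
    MNTCM = "MnTCM"
    MAP = "MAP"
    PWM = "PWM"
    PDM = "PDM"

    @property
    def units(self) -> str:
        return "degC" if self in (Variable.MAT, Variable.MXTWM, Variable.MNTCM) else "mm"


#: canonical ordering used in all tables
VARIABLES = (Variable.MAT, Variable.MXTWM, Variable.MNTCM,
             Variable.MAP, Variable.PWM, Variable.PDM)


class ExtentError(ValueError):
    """A point falls outside a surface's grid extent."""


@dataclass
class ClimateSurface:
    """One gridded variable on a regular geographic lattice.

    ``values`` is (nrows, ncols) with row 0 the northernmost; nodata cells
    hold NaN. Cell membership is half-open: a point on a shared vertical
    edge belongs to the cell to the east, on a shared horizontal edge to
    the cell to the south, making lookup deterministic.
    """

    variable: Variable
    xllcorner: float
    yllcorner: float
    cellsize: float
    values: np.ndarray  # float64, NaN = nodata
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def ymax(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    @property
    def xmax(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    def cell_of(self, point: GeoPoint) -> tuple[int, int]:
        """(row, col) of the containing cell under the half-open convention."""
        col = int(np.floor((point.lon - self.xllcorner) / self.cellsize))
        row = int(np.floor((self.ymax - point.lat) / self.cellsize))
        if not (0 <= col < self.ncols and 0 <= row < self.nrows):
            raise ExtentError(
                f"point ({point.lat}, {point.lon}) outside {self.variable.value} extent")
        return row, col

    def cell_center(self, row: int, col: int) -> GeoPoint:
        return GeoPoint(self.ymax - (row + 0.5) * self.cellsize,
                        self.xllcorner + (col + 0.5) * self.cellsize)


def read_ascii_grid(path, variable: Variable, scale_factor: float = 1.0) -> ClimateSurface:
    """Read an ESRI ASCII grid; raw values are divided by ``scale_factor``."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    nodata = header.get("nodata_value", -9999.0)
    values = np.array([v for row in rows for v in row], dtype=float)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    mask = values == nodata
    values = values / scale_factor
    values[mask] = np.nan
    return ClimateSurface(variable, header["xllcorner"], header["yllcorner"],
                          header["cellsize"], values, nodata)


def write_ascii_grid(surface: ClimateSurface, path) -> None:
    vals = np.where(np.isnan(surface.values), surface.nodata, surface.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {surface.ncols}\nnrows {surface.nrows}\n")
        fh.write(f"xllcorner {surface.xllcorner!r}\nyllcorner {surface.yllcorner!r}\n")
        fh.write(f"cellsize {surface.cellsize!r}\nNODATA_value {surface.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def polygonize(surface: ClimateSurface, merge: bool = True,
               ) -> list[tuple[BaseGeometry, float]]:
    """Convert a raster to searchable polygons with discrete values.

    One rectangle per non-nodata cell, optionally merged where adjacent
    cells share a value (value-preserving); the union covers exactly the
    non-nodata cells. An all-nodata grid gives an empty list and a warning.
    """
    cs = surface.cellsize
    cells: dict[float, list[BaseGeometry]] = {}
    for row in range(surface.nrows):
        for col in range(surface.ncols):
            v = surface.values[row, col]
            if np.isnan(v):
                continue
            x0 = surface.xllcorner + col * cs
            y1 = surface.ymax - row * cs
            cells.setdefault(float(v), []).append(box(x0, y1 - cs, x0 + cs, y1))
    if not cells:
        warnings.warn(f"{surface.variable.value}: all-nodata grid polygonizes to nothing")
        return []
    out: list[tuple[BaseGeometry, float]] = []
    for v in sorted(cells):
        if merge:
            merged = unary_union(cells[v])
            geoms = merged.geoms if merged.geom_type == "MultiPolygon" else [merged]
            out.extend((g, v) for g in geoms)
        else:
            out.extend((g, v) for g in cells[v])
    return out


def query_polygonized(point: GeoPoint, polygons: Sequence[tuple[BaseGeometry, float]],
                      ) -> float | None:
    """Value at a point from a polygonized layer (smallest value on boundary ties)."""
    pt = Point(point.lon, point.lat)
    hits = sorted(v for g, v in polygons if g.covers(pt))
    return hits[0] if hits else None


def extract_value(point: GeoPoint, surface: ClimateSurface) -> float | None:
    """Direct cell lookup; ``None`` for a nodata cell, ExtentError outside."""
    row, col = surface.cell_of(point)
    v = surface.values[row, col]
    return None if np.isnan(v) else float(v)


def extract_at_localities(
        taxon_localities: Sequence[tuple[str, int, GeoPoint, int]],
        surfaces: dict[Variable, ClimateSurface],
) -> tuple[pd.DataFrame, list[str]]:
    """Extract every surface at every (taxon, locality) row.

    Input rows are (taxon, locality_id, point, specimen_count). Missing
    (nodata) extractions are excluded and reported in the returned log,
    never imputed.
    """
    rows, log = [], []
    for taxon, loc_id, pt, n_spec in taxon_localities:
        for var, surf in surfaces.items():
            v = extract_value(pt, surf)
            if v is None:
                log.append(f"{taxon} locality {loc_id}: nodata for {var.value}")
                continue
            rows.append({"taxon": taxon, "locality_id": loc_id,
                         "specimen_count": n_spec, "variable": var.value, "value": v})
    return pd.DataFrame(rows, columns=["taxon", "locality_id", "specimen_count",
                                       "variable", "value"]), log


def _tukey_quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """Median and hinges by the inclusive (Tukey) method.

    For an odd count the median belongs to both halves; the median of an
    even count is the mean of the two central values.
    """
    x = np.sort(x)
    n = len(x)
    med = float(np.median(x))
    half = (n + 1) // 2  # inclusive halves
    return float(np.median(x[:half])), med, float(np.median(x[n - half:]))


def _describe(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = _tukey_quartiles(x)
    return {
        "n": len(x),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "min": float(np.min(x)), "q1": q1, "median": med, "q3": q3,
        "max": float(np.max(x)),
    }


def envelope_stats(extracted: pd.DataFrame, weighting) -> pd.DataFrame:
    """Per-taxon × variable descriptive statistics under one weighting.

    LOCALITY: each locality's value contributes once. SPECIMEN: each value
    is replicated by the taxon's specimen count at that locality, so the
    two weightings coincide exactly when every count is 1. Columns: taxon,
    variable, weighting, n, mean, sd, min, q1, median, q3, max.
    """
    from .habitat import Weighting

    weighting = Weighting(weighting)
    out = []
    for (taxon, var), grp in extracted.groupby(["taxon", "variable"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if weighting is Weighting.SPECIMEN:
            vals = np.repeat(vals, grp["specimen_count"].to_numpy(dtype=int))
        if len(vals) == 0:
            warnings.warn(f"{taxon}: no usable values for {var}; omitted")
            continue
        out.append({"taxon": taxon, "variable": var,
                    "weighting": weighting.value, **_describe(vals)})
    return pd.DataFrame(out, columns=["taxon", "variable", "weighting", "n", "mean",
                                      "sd", "min", "q1", "median", "q3", "max"])


def cross_taxon_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Median/min/max across taxa of the per-taxon mean, per variable × weighting.

    The extreme rows carry the taxa attaining them (alphabetically first on
    exact ties). Input needs columns taxon, variable, weighting, mean.
    """
    if stats.empty:
        raise ValueError("no per-taxon statistics to summarize")
    rows = []
    for (var, wt), grp in stats.groupby(["variable", "weighting"], sort=True):
        grp = grp.sort_values(["mean", "taxon"], kind="mergesort")
        rows.append({
            "variable": var, "weighting": wt,
            "n_taxa": len(grp),
            "median": float(grp["mean"].median()),
            "min": float(grp["mean"].iloc[0]), "min_taxon": grp["taxon"].iloc[0],
            "max": float(grp["mean"].iloc[-1]), "max_taxon": grp["taxon"].iloc[-1],
        })
    return pd.DataFrame(rows, columns=["variable", "weighting", "n_taxa", "median",
                                       "min", "min_taxon", "max", "max_taxon"])
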