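"""Raster/vector data model, grid geometry and file I/O.

Grids are geographic (lon/lat), north-up, with cell (0, 0) at the northwest
corner.  The center of cell (row, col) is::

    lon = origin_lon + (col + 0.5) * cell_size_lon
    lat = origin_lat - (row + 0.5) * cell_size_lat

Rasters are read and written as single- or multi-band GeoTIFFs (each band a
page, georeferencing carried in the standard GeoTIFF tags).  City boundaries
travel as GeoJSON FeatureCollections.  There is no reprojection: grids and
boundaries must agree on their CRS identifier or an error is raised.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("urbanheat")

#: Default geographic CRS identifier used throughout the package.
DEFAULT_CRS = "EPSG:4326"

#: Continents recognised on city boundaries.
CONTINENTS = (
    "Africa",
    "Asia",
    "Europe",
    "North America",
    "South America",
    "Oceania",
)

# GeoTIFF / GDAL TIFF tag codes used for georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

#: LCZ code table: built classes 1-10, natural classes A-G encoded 11-17.
LCZ_CODE_TABLE: dict[int, str] = {
    **{i: f"LCZ {i}" for i in range(1, 11)},
    **{10 + k: f"LCZ {chr(ord('A') + k - 1)}" for k in range(1, 8)},
}

LCZ_CODES = tuple(sorted(LCZ_CODE_TABLE))


class CRSMismatchError(ValueError):
    """Raised when a grid and a boundary carry different CRS identifiers."""


@dataclass
class GeoGrid:
    """A georeferenced continuous raster (MAT, population, GDP ...).

    ``values`` is an ``n_rows x n_cols`` float array with row 0 the
    northernmost row; cells equal to ``nodata`` are missing.
    """

    origin_lon: float
    origin_lat: float
    cell_size_lon: float
    cell_size_lat: float
    values: np.ndarray
    nodata: float = -9999.0
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size_lon <= 0 or self.cell_size_lat <= 0:
            raise ValueError("cell sizes must be positive")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with >= 1 row and column")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-nodata values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        return self.values != self.nodata

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size_lon
        lat = self.origin_lat - (row + 0.5) * self.cell_size_lat
        return lon, lat


@dataclass
class ClassGrid:
    """A georeferenced categorical raster of LCZ class codes."""

    origin_lon: float
    origin_lat: float
    cell_size_lon: float
    cell_size_lat: float
    values: np.ndarray
    nodata_code: int = 0
    code_table: Mapping[int, str] = field(default_factory=lambda: dict(LCZ_CODE_TABLE))
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("class grid values must be integers")
        if self.cell_size_lon <= 0 or self.cell_size_lat <= 0:
            raise ValueError("cell sizes must be positive")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with >= 1 row and column")
        present = set(np.unique(self.values)) - {self.nodata_code}
        unknown = present - set(self.code_table)
        if unknown:
            raise ValueError(f"codes not in code_table: {sorted(unknown)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        return self.values != self.nodata_code

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.origin_lon + (col + 0.5) * self.cell_size_lon
        lat = self.origin_lat - (row + 0.5) * self.cell_size_lat
        return lon, lat


@dataclass
class CityBoundary:
    """One morphological urban area polygon with id, name and continent."""

    city_id: str
    name: str
    continent: str
    geometry: BaseGeometry
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.continent not in CONTINENTS:
            raise ValueError(
                f"unknown continent {self.continent!r}; expected one of {CONTINENTS}"
            )
        if not isinstance(self.geometry, (Polygon, MultiPolygon)):
            raise ValueError("geometry must be a Polygon or MultiPolygon")
        if not self.geometry.is_valid:
            raise ValueError(f"invalid (self-intersecting?) polygon for {self.city_id}")
        if self.geometry.area <= 0:
            raise ValueError(f"polygon for {self.city_id} has zero area")


def boundary_from_rings(
    city_id: str,
    name: str,
    continent: str,
    shell: Sequence[tuple[float, float]],
    holes: Sequence[Sequence[tuple[float, float]]] = (),
) -> CityBoundary:
    """Build a CityBoundary from explicit (lon, lat) rings."""
    return CityBoundary(city_id, name, continent, Polygon(shell, holes))


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

def cell_centers_in_polygon(
    grid: GeoGrid | ClassGrid, boundary: CityBoundary
) -> list[tuple[int, int]]:
    """Indices of cells whose center lies inside the boundary polygon.

    A center exactly on the polygon edge counts as inside (``covers``
    semantics).  The result is in deterministic row-major order; an empty
    list is legal.  Raises :class:`CRSMismatchError` when the grid and the
    boundary disagree on CRS.
    """
    if grid.crs_id != boundary.crs_id:
        raise CRSMismatchError(
            f"grid CRS {grid.crs_id!r} does not match boundary CRS "
            f"{boundary.crs_id!r}"
        )
    geom = boundary.geometry
    min_lon, min_lat, max_lon, max_lat = geom.bounds

    # Restrict to rows/cols whose centers could fall inside the bbox.
    col_lo = max(0, math.floor((min_lon - grid.origin_lon) / grid.cell_size_lon - 0.5))
    col_hi = min(
        grid.n_cols - 1,
        math.ceil((max_lon - grid.origin_lon) / grid.cell_size_lon - 0.5),
    )
    row_lo = max(0, math.floor((grid.origin_lat - max_lat) / grid.cell_size_lat - 0.5))
    row_hi = min(
        grid.n_rows - 1,
        math.ceil((grid.origin_lat - min_lat) / grid.cell_size_lat - 0.5),
    )
    if col_lo > col_hi or row_lo > row_hi:
        return []

    rows = np.arange(row_lo, row_hi + 1)
    cols = np.arange(col_lo, col_hi + 1)
    lons = grid.origin_lon + (cols + 0.5) * grid.cell_size_lon
    lats = grid.origin_lat - (rows + 0.5) * grid.cell_size_lat
    lon_m, lat_m = np.meshgrid(lons, lats)
    pts = shapely.points(lon_m.ravel(), lat_m.ravel())
    prep = shapely.prepare(geom)  # noqa: F841 - prepares in place
    inside = shapely.covers(geom, pts).reshape(lat_m.shape)
    rr, cc = np.nonzero(inside)
    return [(int(rows[i]), int(cols[j])) for i, j in zip(rr, cc)]


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile)
# ---------------------------------------------------------------------------

def _geokey_directory(crs_id: str) -> tuple[int, ...]:
    """Minimal GeoKey directory for a geographic EPSG CRS."""
    epsg = int(crs_id.split(":")[1]) if ":" in crs_id else int(crs_id)
    # header (version 1.1.0, 3 keys); ModelType=geographic, RasterType=area
    return (
        1, 1, 0, 3,
        1024, 0, 1, 2,
        1025, 0, 1, 1,
        2048, 0, 1, epsg,
    )


def _geo_extratags(grid: GeoGrid | ClassGrid, nodata) -> list[tuple]:
    return [
        (
            _TAG_MODEL_PIXEL_SCALE,
            "d",
            3,
            (grid.cell_size_lon, grid.cell_size_lat, 0.0),
        ),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0),
        ),
        (_TAG_GEO_KEY_DIRECTORY, "H", 16, _geokey_directory(grid.crs_id)),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
    ]


def write_raster(path: str | Path, grid: GeoGrid | ClassGrid) -> None:
    """Write a grid as a single-band GeoTIFF (float64 or int32)."""
    write_raster_stack(path, [grid])


def write_raster_stack(path: str | Path, grids: Sequence[GeoGrid | ClassGrid]) -> None:
    """Write several same-shape grids as the bands (pages) of one GeoTIFF."""
    if not grids:
        raise ValueError("need at least one grid")
    with tifffile.TiffWriter(str(path)) as tif:
        for grid in grids:
            if isinstance(grid, ClassGrid):
                data = grid.values.astype(np.int32)
                nodata = int(grid.nodata_code)
            else:
                data = grid.values.astype(np.float64)
                nodata = grid.nodata
            tif.write(data, extratags=_geo_extratags(grid, nodata))


def read_raster(
    path: str | Path,
    band: int = 0,
    *,
    categorical: bool | None = None,
    code_table: Mapping[int, str] | None = None,
) -> GeoGrid | ClassGrid:
    """Read one band of a GeoTIFF as a :class:`GeoGrid` or :class:`ClassGrid`.

    ``categorical`` defaults to the stored dtype (integer -> ClassGrid).
    Non-north-up files (rotated/sheared ModelTransformation) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        if band < 0 or band >= len(tif.pages):
            raise IndexError(f"band {band} out of range (file has {len(tif.pages)})")
        page = tif.pages[band]
        tags = {t.code: t.value for t in page.tags.values()}
        if _TAG_MODEL_TRANSFORMATION in tags:
            raise ValueError(
                f"{path}: ModelTransformation present; only north-up "
                "scale+tiepoint georeferencing is supported"
            )
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE]
        tie = tags[_TAG_MODEL_TIEPOINT]
        if tie[0] != 0 or tie[1] != 0:
            raise ValueError(f"{path}: tiepoint must anchor raster pixel (0, 0)")
        origin_lon, origin_lat = tie[3], tie[4]
        crs_id = DEFAULT_CRS
        if _TAG_GEO_KEY_DIRECTORY in tags:
            kd = tags[_TAG_GEO_KEY_DIRECTORY]
            for k in range(4, len(kd), 4):
                if kd[k] == 2048:
                    crs_id = f"EPSG:{kd[k + 3]}"
        values = page.asarray()
        nodata_raw = tags.get(_TAG_GDAL_NODATA)

    is_int = np.issubdtype(values.dtype, np.integer)
    if categorical is None:
        categorical = is_int
    if categorical:
        nodata_code = int(float(nodata_raw)) if nodata_raw is not None else 0
        return ClassGrid(
            origin_lon, origin_lat, sx, sy,
            values.astype(np.int64),
            nodata_code=nodata_code,
            code_table=dict(code_table or LCZ_CODE_TABLE),
            crs_id=crs_id,
        )
    nodata = float(nodata_raw) if nodata_raw is not None else -9999.0
    return GeoGrid(origin_lon, origin_lat, sx, sy, values, nodata=nodata, crs_id=crs_id)


# ---------------------------------------------------------------------------
# Boundary I/O (GeoJSON)
# ---------------------------------------------------------------------------

_REQUIRED_PROPS = ("city_id", "name", "continent")


def read_boundaries(path: str | Path) -> list[CityBoundary]:
    """Read a GeoJSON FeatureCollection of city boundary polygons.

    Every feature must carry ``city_id``, ``name`` and ``continent``
    properties and a Polygon or MultiPolygon geometry.  MultiPolygons are
    retained as multi-part boundaries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    boundaries: list[CityBoundary] = []
    seen: set[str] = set()
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        for key in _REQUIRED_PROPS:
            if key not in props or props[key] in (None, ""):
                raise ValueError(f"feature {i}: missing required attribute {key!r}")
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise ValueError(f"feature {i}: geometry must be Polygon or MultiPolygon")
        cb = CityBoundary(
            str(props["city_id"]), str(props["name"]), str(props["continent"]), geom
        )
        if cb.city_id in seen:
            raise ValueError(f"duplicate city_id {cb.city_id!r}")
        seen.add(cb.city_id)
        boundaries.append(cb)
    return boundaries


def write_boundaries(path: str | Path, boundaries: Sequence[CityBoundary]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "city_id": b.city_id,
                "name": b.name,
                "continent": b.continent,
            },
            "geometry": mapping(b.geometry),
        }
        for b in boundaries
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))
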