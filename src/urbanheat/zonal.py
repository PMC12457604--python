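"""Citywide raster aggregation: zonal means, sums and categorical shares.

All statistics follow the cell-center inclusion rule of
:func:`urbanheat.core_geo.cell_centers_in_polygon`: a raster cell belongs to
a city iff its center lies inside (or exactly on the edge of) the city
polygon.  Means are unweighted cell means — at city scale on ~1 km
geographic grids the cosine-latitude variation across a single city is
negligible; a latitude-weighted mode is available via ``weighted=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core_geo import (
    LCZ_CODES,
    CityBoundary,
    ClassGrid,
    GeoGrid,
    cell_centers_in_polygon,
)

logger = logging.getLogger("urbanheat")

#: Default LCZ grouping used for the morphology comparison.  The group
#: labels follow standard LCZ semantics: compact built forms (1-3), open
#: built forms (4-6), then the remaining built classes individually, and
#: natural covers split into green (A-C = trees/bush), low plants (D),
#: bare natural surfaces (E rock/paved-natural, F bare soil) and water (G).
DEFAULT_GROUPING: dict[str, frozenset[int]] = {
    "compact": frozenset({1, 2, 3}),
    "open": frozenset({4, 5, 6}),
    "lightweight": frozenset({7}),
    "large_lowrise": frozenset({8}),
    "sparse": frozenset({9}),
    "industry": frozenset({10}),
    "green": frozenset({11, 12, 13}),
    "low_plants": frozenset({14}),
    "bare_natural": frozenset({15, 16}),
    "water": frozenset({17}),
}


@dataclass
class LCZProfile:
    """Per-city LCZ composition: share of classified city area per code."""

    city_id: str
    shares: dict[int, float]
    n_cells: int
    grouped_shares: dict[str, float] = field(default_factory=dict)


def _included_values(grid: GeoGrid, boundary: CityBoundary) -> np.ndarray:
    cells = cell_centers_in_polygon(grid, boundary)
    if not cells:
        return np.empty(0)
    idx = np.array(cells)
    vals = grid.values[idx[:, 0], idx[:, 1]]
    return vals[vals != grid.nodata]


def zonal_mean(
    grid: GeoGrid, boundary: CityBoundary, *, weighted: bool = False
) -> float | None:
    """Arithmetic mean of non-nodata cells inside the boundary.

    Returns None (flagged missing, logged) when no valid cell center falls
    inside the polygon.  ``weighted=True`` applies cos(latitude) weights.
    """
    cells = cell_centers_in_polygon(grid, boundary)
    if not cells:
        logger.warning("zonal_mean: no cells inside %s", boundary.city_id)
        return None
    idx = np.array(cells)
    vals = grid.values[idx[:, 0], idx[:, 1]]
    ok = vals != grid.nodata
    if not ok.any():
        logger.warning("zonal_mean: all cells nodata for %s", boundary.city_id)
        return None
    if weighted:
        lats = grid.origin_lat - (idx[:, 0] + 0.5) * grid.cell_size_lat
        w = np.cos(np.deg2rad(lats))[ok]
        return float(np.sum(vals[ok] * w) / np.sum(w))
    return float(vals[ok].mean())


def zonal_sum(grid: GeoGrid, boundary: CityBoundary) -> float | None:
    """Sum of cells inside the boundary; nodata cells contribute 0."""
    cells = cell_centers_in_polygon(grid, boundary)
    if not cells:
        logger.warning("zonal_sum: no cells inside %s", boundary.city_id)
        return None
    idx = np.array(cells)
    vals = grid.values[idx[:, 0], idx[:, 1]]
    return float(vals[vals != grid.nodata].sum())


def class_shares(grid: ClassGrid, boundary: CityBoundary) -> LCZProfile | None:
    """LCZ share profile over classified (non-nodata) cells in the city.

    Shares are explicit for all codes in the grid's code table (zero when a
    class is absent); nodata/unclassified cells shrink the denominator
    rather than forming a pseudo-class.
    """
    cells = cell_centers_in_polygon(grid, boundary)
    if not cells:
        logger.warning("class_shares: no cells inside %s", boundary.city_id)
        return None
    idx = np.array(cells)
    vals = grid.values[idx[:, 0], idx[:, 1]]
    vals = vals[vals != grid.nodata_code]
    if vals.size == 0:
        logger.warning("class_shares: all cells unclassified for %s", boundary.city_id)
        return None
    codes = sorted(grid.code_table)
    counts = {c: int(np.count_nonzero(vals == c)) for c in codes}
    n = int(vals.size)
    shares = {c: counts[c] / n for c in codes}
    return LCZProfile(city_id=boundary.city_id, shares=shares, n_cells=n)


def group_shares(
    profile: LCZProfile, grouping: Mapping[str, Iterable[int]] = DEFAULT_GROUPING
) -> dict[str, float]:
    """Aggregate an LCZ profile into labelled groups (sums of member shares).

    Groups must be disjoint; groups with no member present map to 0.
    """
    seen: set[int] = set()
    for label, members in grouping.items():
        members = set(members)
        if seen & members:
            raise ValueError(f"grouping is not disjoint at group {label!r}")
        seen |= members
    out = {
        label: float(sum(profile.shares.get(c, 0.0) for c in members))
        for label, members in grouping.items()
    }
    profile.grouped_shares = out
    return out
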