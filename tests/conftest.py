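import numpy as np
import pytest
from shapely.geometry import Polygon

from urbanheat import CityBoundary, GeoGrid, WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact zero-noise synthetic world shared across read-only tests."""
    return generate_world(WorldConfig(n_cities=24, n_hot_cities=6, seed=11))


@pytest.fixture
def grid4():
    """4x4 unit-degree grid with values 0..15, origin at (0, 4)."""
    return GeoGrid(0.0, 4.0, 1.0, 1.0, np.arange(16, dtype=float).reshape(4, 4))


def make_boundary(shell, city_id="c1", continent="Europe"):
    return CityBoundary(city_id, city_id, continent, Polygon(shell))


def brute_force_cells(grid, boundary):
    """Oracle: point-in-polygon test of every cell center, row-major."""
    out = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            lon, lat = grid.cell_center(r, c)
            from shapely.geometry import Point

            if boundary.geometry.covers(Point(lon, lat)):
                out.append((r, c))
    return out


def random_polygon(rng, lon_range=(0.0, 20.0), lat_range=(0.0, 20.0)):
    """A random simple polygon: convex hull of 4-10 random points."""
    from shapely.geometry import MultiPoint

    npts = rng.integers(4, 11)
    pts = np.column_stack(
        [rng.uniform(*lon_range, npts), rng.uniform(*lat_range, npts)]
    )
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        return random_polygon(rng, lon_range, lat_range)
    return hull
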