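"""Grid geometry, containment rule and GeoTIFF/GeoJSON round trips."""

import numpy as np
import pytest
import tifffile
from shapely.geometry import MultiPolygon, Polygon, box

from urbanheat import (
    CityBoundary,
    ClassGrid,
    CRSMismatchError,
    GeoGrid,
    cell_centers_in_polygon,
    read_boundaries,
    read_raster,
    write_boundaries,
    write_raster,
    write_raster_stack,
)

from conftest import brute_force_cells, make_boundary, random_polygon


class TestCellCenters:
    def test_interior_block(self, grid4):
        # rectangle covering exactly the interior 2x2 block of centers
        b = make_boundary([(1, 1), (3, 1), (3, 3), (1, 3)])
        assert cell_centers_in_polygon(grid4, b) == [(1, 1), (1, 2), (2, 1), (2, 2)]

    def test_polygon_between_centers_is_empty(self, grid4):
        b = make_boundary([(1.6, 1.6), (2.4, 1.6), (2.4, 2.4), (1.6, 2.4)])
        assert cell_centers_in_polygon(grid4, b) == []

    def test_center_on_edge_counts_inside(self, grid4):
        # polygon edge passes exactly through the (1, 1) center at lon/lat 1.5, 2.5
        b = make_boundary([(1.5, 2.5), (3, 2.5), (3, 4), (1.5, 4)])
        assert (1, 1) in cell_centers_in_polygon(grid4, b)

    def test_crs_mismatch_names_both(self, grid4):
        b = make_boundary([(1, 1), (3, 1), (3, 3), (1, 3)])
        b.crs_id = "EPSG:3857"
        with pytest.raises(CRSMismatchError, match="EPSG:4326.*EPSG:3857"):
            cell_centers_in_polygon(grid4, b)

    def test_random_polygons_match_brute_force(self):
        rng = np.random.default_rng(42)
        grid = GeoGrid(0.0, 20.0, 1.0, 1.0, np.zeros((20, 20)))
        for _ in range(50):
            b = make_boundary(random_polygon(rng).exterior.coords)
            assert cell_centers_in_polygon(grid, b) == brute_force_cells(grid, b)

    def test_nested_polygon_subset(self):
        rng = np.random.default_rng(7)
        grid = GeoGrid(0.0, 20.0, 1.0, 1.0, np.zeros((20, 20)))
        for _ in range(20):
            outer = random_polygon(rng)
            inner = outer.buffer(-rng.uniform(0.1, 2.0))
            if inner.is_empty or inner.geom_type != "Polygon":
                continue
            outer_cells = set(cell_centers_in_polygon(grid, make_boundary(outer.exterior.coords)))
            inner_cells = set(cell_centers_in_polygon(grid, make_boundary(inner.exterior.coords)))
            assert inner_cells <= outer_cells


class TestRasterIO:
    def test_int_round_trip(self, tmp_path):
        grid = ClassGrid(5.0, 8.0, 0.5, 0.25, np.array([[1, 2, 3], [4, 5, 0], [16, 17, 1]]))
        p = tmp_path / "g.tif"
        write_raster(p, grid)
        back = read_raster(p)
        assert isinstance(back, ClassGrid)
        np.testing.assert_array_equal(back.values, grid.values)
        assert (back.origin_lon, back.origin_lat) == (5.0, 8.0)
        assert (back.cell_size_lon, back.cell_size_lat) == (0.5, 0.25)
        assert back.nodata_code == 0
        assert back.crs_id == "EPSG:4326"

    def test_float_round_trip(self, tmp_path):
        vals = np.array([[1.5, -9999.0], [2.25, 3.125]])
        grid = GeoGrid(-10.0, 50.0, 0.1, 0.1, vals)
        p = tmp_path / "f.tif"
        write_raster(p, grid)
        back = read_raster(p, categorical=False)
        np.testing.assert_array_equal(back.values, vals)
        assert back.nodata == -9999.0

    def test_second_band(self, tmp_path):
        g1 = GeoGrid(0, 2, 1, 1, np.ones((2, 2)))
        g2 = GeoGrid(0, 2, 1, 1, np.full((2, 2), 7.0))
        p = tmp_path / "two.tif"
        write_raster_stack(p, [g1, g2])
        assert read_raster(p, band=1, categorical=False).values[0, 0] == 7.0

    def test_nodata_excluded_from_stats(self, tmp_path):
        vals = np.array([[1.0, -9999.0], [3.0, -9999.0]])
        p = tmp_path / "n.tif"
        write_raster(p, GeoGrid(0, 2, 1, 1, vals))
        back = read_raster(p, categorical=False)
        assert back.mask().sum() == 2  # oracle scan: exactly two valid cells

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raster(tmp_path / "nope.tif")

    def test_rotated_transform_rejected(self, tmp_path):
        p = tmp_path / "rot.tif"
        transform = (0.0, 1.0, 0, 5.0, 1.0, 0.0, 0, 5.0, 0, 0, 1.0, 0, 0, 0, 0, 1.0)
        with tifffile.TiffWriter(str(p)) as tif:
            tif.write(np.zeros((3, 3)), extratags=[(34264, "d", 16, transform)])
        with pytest.raises(ValueError, match="north-up"):
            read_raster(p)


class TestBoundaryIO:
    def _three(self):
        return [
            CityBoundary(f"c{i}", f"City {i}", "Asia", box(i * 3, 0, i * 3 + 2, 2))
            for i in range(3)
        ]

    def test_round_trip_ids(self, tmp_path):
        p = tmp_path / "b.geojson"
        write_boundaries(p, self._three())
        back = read_boundaries(p)
        assert [b.city_id for b in back] == ["c0", "c1", "c2"]
        assert all(b.continent == "Asia" for b in back)

    def test_missing_continent_names_field(self, tmp_path):
        import json

        p = tmp_path / "bad.geojson"
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"city_id": "x", "name": "X"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]],
                    },
                }
            ],
        }
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="feature 0.*continent"):
            read_boundaries(p)

    def test_multipolygon_cells_are_union_of_parts(self, tmp_path):
        grid = GeoGrid(0.0, 10.0, 1.0, 1.0, np.zeros((10, 10)))
        a = box(0.2, 0.2, 2.8, 2.8)
        b = box(6.2, 6.2, 8.8, 8.8)
        multi = CityBoundary("m", "M", "Africa", MultiPolygon([a, b]))
        pa = make_boundary(a.exterior.coords, "a")
        pb = make_boundary(b.exterior.coords, "b")
        union = set(cell_centers_in_polygon(grid, pa)) | set(
            cell_centers_in_polygon(grid, pb)
        )
        assert set(cell_centers_in_polygon(grid, multi)) == union

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError, match="invalid"):
            CityBoundary("x", "X", "Asia", bowtie)
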