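"""Raster/vector I/O, alignment and rasterization contracts."""

import numpy as np
import pandas as pd
import pytest
import shapely
import tifffile
from shapely.geometry import LineString, Point, Polygon, box

from chw_access.geodata import (
    Grid,
    VectorLayer,
    align_stack,
    make_grid,
    rasterize,
    read_facilities,
    read_geojson,
    read_grid,
    read_roster,
    write_geojson,
    write_grid,
)
from helpers_oracles import point_segment_distance


class TestGridIO:
    def test_identity_read(self, tmp_path):
        g = make_grid(np.arange(25, dtype=float).reshape(5, 5), 100.0)
        p = tmp_path / "g.tif"
        write_grid(p, g)
        r = read_grid(p, expected_cell_size=100.0)
        assert r.shape == (5, 5)
        assert r.cell_size == 100.0

    def test_round_trip_bit_exact(self, tmp_path, rng):
        vals = rng.standard_normal((7, 9))
        g = make_grid(vals, 100.0, x0=12345.5, y0=67890.25, nodata=-9999.0)
        p = tmp_path / "g.tif"
        write_grid(p, g)
        r = read_grid(p)
        np.testing.assert_array_equal(r.values, vals)
        assert r.transform == g.transform
        assert r.nodata == -9999.0
        assert r.crs_id == g.crs_id

    def test_nan_nodata_round_trip(self, tmp_path):
        g = make_grid(np.ones((3, 3)), 50.0)
        write_grid(tmp_path / "g.tif", g)
        assert np.isnan(read_grid(tmp_path / "g.tif").nodata)

    def test_rotated_transform_rejected(self, tmp_path):
        p = tmp_path / "rot.tif"
        m = np.array([[100.0, 5.0, 0, 0], [5.0, -100.0, 0, 1000.0], [0, 0, 0, 0], [0, 0, 0, 1]])
        tifffile.imwrite(str(p), np.zeros((4, 4)), extratags=[(34264, "d", 16, tuple(m.ravel()))])
        with pytest.raises(ValueError, match="non-north-up"):
            read_grid(p)

    def test_geographic_crs_rejected(self, tmp_path):
        g = make_grid(np.zeros((3, 3)), 100.0, crs_id="EPSG:4326")
        p = tmp_path / "geo.tif"
        write_grid(p, g)
        with pytest.raises(ValueError, match="degree-unit"):
            read_grid(p)

    def test_wrong_cell_size_rejected(self, tmp_path):
        g = make_grid(np.zeros((3, 3)), 30.0)
        write_grid(tmp_path / "g.tif", g)
        with pytest.raises(ValueError, match="cell size"):
            read_grid(tmp_path / "g.tif", expected_cell_size=100.0)

    def test_missing_georeferencing_rejected(self, tmp_path):
        tifffile.imwrite(str(tmp_path / "plain.tif"), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="georeferencing"):
            read_grid(tmp_path / "plain.tif")


class TestGridGeometry:
    def test_rotation_in_constructor_rejected(self):
        with pytest.raises(ValueError, match="non-north-up"):
            Grid(np.zeros((3, 3)), (0.0, 100.0, 2.0, 300.0, 0.0, -100.0), 100.0)

    def test_cell_center_round_trip(self):
        g = make_grid(np.zeros((10, 10)), 100.0)
        for rc in [(0, 0), (3, 7), (9, 9)]:
            assert g.index_of(*g.center_of(*rc)) == rc

    def test_point_outside_extent(self):
        g = make_grid(np.zeros((5, 5)), 100.0)
        with pytest.raises(ValueError, match="outside"):
            g.index_of(-1.0, 100.0)


class TestAlignStack:
    def test_nearest_upsampling_replicates_blocks(self):
        coarse = make_grid(np.arange(4, dtype=float).reshape(2, 2), 300.0)
        ref = make_grid(np.zeros((6, 6)), 100.0)
        (out,) = align_stack([coarse], ref, ["nearest"])
        expected = np.kron(coarse.values, np.ones((3, 3)))
        np.testing.assert_array_equal(out.values, expected)

    def test_constant_grid_invariant(self):
        src = make_grid(np.full((30, 30), 7.5), 30.0, y0=900.0)
        ref = make_grid(np.zeros((9, 9)), 100.0, y0=900.0)
        for mode in ("nearest", "bilinear"):
            (out,) = align_stack([src], ref, [mode])
            np.testing.assert_allclose(out.values, 7.5)

    def test_bilinear_preserves_plane(self):
        # z = x on a 30 m grid resampled to 100 m: a plane is reproduced
        # exactly by bilinear interpolation of cell centers
        rows = cols = 40
        fine = make_grid(np.zeros((rows, cols)), 30.0, y0=rows * 30.0)
        cx, _ = fine.cell_centers()
        fine = fine.with_values(cx)
        ref = make_grid(np.zeros((10, 10)), 100.0, x0=60.0, y0=1060.0)
        (out,) = align_stack([fine], ref, ["bilinear"])
        rx, _ = ref.cell_centers()
        np.testing.assert_allclose(out.values, rx, rtol=1e-12)

    def test_idempotent_on_aligned_grid(self, rng):
        ref = make_grid(rng.standard_normal((8, 8)), 100.0)
        (out,) = align_stack([ref], ref, ["bilinear"])
        np.testing.assert_array_equal(out.values, ref.values)

    def test_disjoint_extents_error(self):
        far = make_grid(np.zeros((5, 5)), 100.0, x0=10_000.0)
        ref = make_grid(np.zeros((5, 5)), 100.0)
        with pytest.raises(ValueError, match="disjoint"):
            align_stack([far], ref, ["nearest"])


class TestRasterize:
    def test_horizontal_line_burns_row(self):
        ref = make_grid(np.zeros((5, 5)), 100.0)
        y = ref.center_of(2, 0)[1]
        layer = VectorLayer([(LineString([(0, y), (500, y)]), {})], ref.crs_id)
        out = rasterize(layer, ref)
        expected = np.zeros((5, 5))
        expected[2, :] = 1.0
        np.testing.assert_array_equal(out.values, expected)

    def test_polygon_covering_extent_burns_everything(self):
        ref = make_grid(np.zeros((4, 4)), 100.0)
        layer = VectorLayer([(box(-10, -10, 500, 500), {"v": 3})], ref.crs_id)
        out = rasterize(layer, ref, burn_value_field="v")
        np.testing.assert_array_equal(out.values, np.full((4, 4), 3.0))

    def test_crossing_roads_match_distance_oracle(self):
        ref = make_grid(np.zeros((12, 12)), 100.0)
        segs = [((150, 100), (1050, 1100)), ((100, 1000), (1100, 150))]
        layer = VectorLayer(
            [(LineString([a, b]), {}) for a, b in segs], ref.crs_id
        )
        out = rasterize(layer, ref)
        cx, cy = ref.cell_centers()
        half = ref.cell_size / 2
        expected = np.zeros(ref.shape)
        for r in range(12):
            for c in range(12):
                d = min(
                    point_segment_distance(cx[r, c], cy[r, c], a[0], a[1], b[0], b[1])
                    for a, b in segs
                )
                if d <= half:
                    expected[r, c] = 1.0
        np.testing.assert_array_equal(out.values, expected)

    def test_line_raster_stays_near_geometry(self, rng):
        # every burned cell center is within half a cell of the line
        ref = make_grid(np.zeros((15, 15)), 100.0)
        pts = rng.uniform(50, 1450, size=(4, 2))
        line = LineString(pts)
        out = rasterize(VectorLayer([(line, {})], ref.crs_id), ref)
        cx, cy = ref.cell_centers()
        rows, cols = np.nonzero(out.values > 0)
        assert rows.size > 0
        for r, c in zip(rows, cols):
            assert line.distance(Point(cx[r, c], cy[r, c])) <= ref.cell_size / 2 + 1e-9

    def test_point_burns_containing_cell(self):
        ref = make_grid(np.zeros((5, 5)), 100.0)
        out = rasterize(VectorLayer([(Point(250, 250), {})], ref.crs_id), ref)
        assert out.values[2, 2] == 1.0
        assert out.values.sum() == 1.0

    def test_empty_layer_warns_all_nodata(self):
        ref = make_grid(np.zeros((5, 5)), 100.0)
        with pytest.warns(UserWarning, match="empty layer"):
            out = rasterize(VectorLayer([], ref.crs_id), ref)
        assert (out.values == 0).all()


class TestVectorsAndTables:
    def test_geojson_round_trip(self, tmp_path):
        layer = VectorLayer(
            [
                (Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), {"fokontany_id": "f1"}),
                (LineString([(0, 0), (2, 2)]), {"road_id": "r1"}),
            ],
            "EPSG:32738",
        )
        write_geojson(tmp_path / "l.geojson", layer)
        r = read_geojson(tmp_path / "l.geojson")
        assert r.crs_id == "EPSG:32738"
        assert len(r) == 2
        assert r.features[0][0].equals(layer.features[0][0])
        assert r.attribute("fokontany_id")[0] == "f1"

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError, match="invalid polygon"):
            VectorLayer([(bowtie, {})])

    def test_roster_validation(self, tmp_path):
        p = tmp_path / "roster.csv"
        pd.DataFrame(
            {
                "fokontany_id": ["a", "a"],
                "n_acs": [2, 2],
                "assigned_csb_id": ["c1", "c1"],
                "assigned_pa_id": ["p1", None],
            }
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="unique"):
            read_roster(p)

    def test_facility_kind_validation(self, tmp_path):
        p = tmp_path / "fac.csv"
        pd.DataFrame(
            {"facility_id": ["x"], "kind": ["CLINIC"], "x": [0.0], "y": [0.0]}
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="unknown facility kinds"):
            read_facilities(p)
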