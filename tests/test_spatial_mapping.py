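"""Raster I/O, per-pixel R0 mapping, CI layers and overlay validation."""

import numpy as np
import pytest

from irmap import (
    RasterGrid,
    ResistancePoint,
    annual_aggregate,
    ci_rasters,
    classify_map,
    overlay_accuracy,
    r0_map,
    read_ascii_grid,
    read_points_csv,
    write_ascii_grid,
    write_points_csv,
)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path, make_grid):
        g = make_grid([[1.25, -2.5], [3.0, 4.75]], origin=(-20.0, -35.0), cellsize=0.5)
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        back = read_ascii_grid(path)
        assert np.allclose(back.values, g.values, atol=1e-6)
        assert back.origin == g.origin
        assert back.cellsize == g.cellsize
        assert back.nodata == g.nodata

    def test_nodata_cells_round_trip_as_nan(self, tmp_path, make_grid):
        g = make_grid([[1.0, np.nan], [np.nan, 4.0]])
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        text = path.read_text()
        assert "NODATA_value -9999" in text
        assert "-9999" in text.splitlines()[6]
        back = read_ascii_grid(path)
        assert np.isnan(back.values[0, 1]) and np.isnan(back.values[1, 0])

    def test_first_data_row_is_northernmost(self, tmp_path):
        # 2x1 grid over latitudes [0, 2): north cell holds 9, south holds 1
        path = tmp_path / "g.asc"
        path.write_text(
            "ncols 1\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n9\n1\n"
        )
        g = read_ascii_grid(path)
        assert g.values[0, 0] == 9.0
        assert g.cell_index(0.5, 1.5) == (0, 0)  # northern point -> first row
        assert g.cell_index(0.5, 0.5) == (1, 0)

    def test_malformed_header_names_missing_key(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 2\nxllcorner 0\ncellsize 1\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="yllcorner"):
            read_ascii_grid(path)

    def test_point_lookup_half_open_cells(self, make_grid):
        g = make_grid(np.zeros((2, 2)), origin=(0.0, 0.0), cellsize=1.0)
        assert g.cell_index(0.0, 0.0) == (1, 0)  # lower-left boundary belongs
        assert g.cell_index(2.0, 1.0) is None  # right boundary falls off-grid
        assert g.cell_index(1.0, 2.0) is None  # top boundary falls off-grid

    def test_nodata_sentinel_collision_rejected(self):
        with pytest.raises(ValueError, match="sentinel"):
            RasterGrid(values=np.array([[-9999.0]]), origin=(0, 0), cellsize=1.0)


class TestR0Map:
    def test_single_pixel_matches_point_evaluation(self, table1_params, parham_lh, make_grid):
        temp = make_grid([[25.0]])
        rain = make_grid([[25.0]])
        out = r0_map(temp, rain, table1_params, parham_lh)
        assert out.values[0, 0] == pytest.approx(1.874, abs=5e-4)

    def test_nodata_propagates(self, table1_params, parham_lh, make_grid):
        temp = make_grid([[25.0, 25.0]])
        rain = make_grid([[np.nan, np.nan]])
        out = r0_map(temp, rain, table1_params, parham_lh)
        assert np.all(np.isnan(out.values))

    def test_pixelwise_independence_under_permutation(self, table1_params, parham_lh, make_grid, rng):
        temp_v = rng.uniform(15, 35, (4, 5))
        rain_v = rng.uniform(0, 60, (4, 5))
        out = r0_map(make_grid(temp_v), make_grid(rain_v), table1_params, parham_lh)
        perm = rng.permutation(20)
        temp_p = temp_v.ravel()[perm].reshape(4, 5)
        rain_p = rain_v.ravel()[perm].reshape(4, 5)
        out_p = r0_map(make_grid(temp_p), make_grid(rain_p), table1_params, parham_lh)
        assert np.allclose(
            out_p.values.ravel(), out.values.ravel()[perm], equal_nan=True
        )

    def test_grid_mismatch_names_attribute(self, table1_params, parham_lh, make_grid):
        temp = make_grid(np.zeros((2, 2)))
        rain_shape = make_grid(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="shape"):
            r0_map(temp, rain_shape, table1_params, parham_lh)
        rain_origin = make_grid(np.zeros((2, 2)), origin=(1.0, 0.0))
        with pytest.raises(ValueError, match="origin"):
            r0_map(temp, rain_origin, table1_params, parham_lh)

    def test_printed_mortality_coefficient_maps_to_all_nodata(self, table1_params, printed_lh, make_grid):
        temp = make_grid([[20.0, 30.0]])
        rain = make_grid([[25.0, 25.0]])
        out = r0_map(temp, rain, table1_params, printed_lh)
        assert np.all(np.isnan(out.values))


class TestClassifyMap:
    def test_threshold_codes(self, make_grid):
        out = classify_map(make_grid([[0.5, 1.05, 1.2]]))
        assert np.array_equal(out.values, [[1.0, 2.0, 3.0]])

    def test_all_nodata_in_all_nodata_out(self, make_grid):
        out = classify_map(make_grid([[np.nan, np.nan]]))
        assert np.all(np.isnan(out.values))


class TestAnnualAggregate:
    def test_identity_on_identical_months(self, make_grid, rng):
        g = make_grid(rng.random((3, 3)))
        out = annual_aggregate([g] * 12)
        assert np.allclose(out.values, g.values)

    def test_pixelwise_mean(self, make_grid):
        months = [make_grid([[1.0]])] * 6 + [make_grid([[2.0]])] * 6
        assert annual_aggregate(months).values[0, 0] == pytest.approx(1.5)

    def test_nodata_month_excluded_from_mean(self, make_grid):
        months = [make_grid([[2.0]])] * 11 + [make_grid([[np.nan]])]
        assert annual_aggregate(months).values[0, 0] == pytest.approx(2.0)

    def test_wrong_month_count_is_an_error(self, make_grid):
        with pytest.raises(ValueError, match="12"):
            annual_aggregate([make_grid([[1.0]])] * 11)


class TestCiRasters:
    def test_constant_months_give_zero_width(self, make_grid):
        pair = ci_rasters([make_grid([[3.0]])] * 12)
        assert pair.lower.values[0, 0] == pytest.approx(3.0)
        assert pair.upper.values[0, 0] == pytest.approx(3.0)
        assert pair.sd.values[0, 0] == 0.0

    def test_hand_computed_sample_sd(self, make_grid):
        months = [make_grid([[1.0]])] * 6 + [make_grid([[2.0]])] * 6
        pair = ci_rasters(months)
        sd = np.sqrt(3 / 11)  # n-1 divisor
        assert pair.sd.values[0, 0] == pytest.approx(sd, rel=1e-12)
        assert pair.lower.values[0, 0] == pytest.approx(1.5 - 1.96 * sd, rel=1e-12)
        assert pair.upper.values[0, 0] == pytest.approx(1.5 + 1.96 * sd, rel=1e-12)

    def test_width_identity_and_shift_invariance(self, make_grid, rng):
        months = [make_grid(rng.random((4, 4))) for _ in range(12)]
        pair = ci_rasters(months)
        width = pair.upper.values - pair.lower.values
        assert np.allclose(width, 2 * 1.96 * pair.sd.values)
        shifted = ci_rasters([m.with_values(m.values + 5.0) for m in months])
        assert np.allclose(
            shifted.upper.values - shifted.lower.values, width, atol=1e-12
        )


def _points(coords, status="resistant"):
    return [ResistancePoint(lon, lat, 2019, status) for lon, lat in coords]


class TestOverlay:
    def classmap(self, make_grid):
        # 2x2: north row high (3), south row low (1)
        return make_grid([[3.0, 3.0], [1.0, 1.0]], origin=(0.0, 0.0), cellsize=1.0)

    def test_all_points_in_target(self, make_grid):
        cm = self.classmap(make_grid)
        res = overlay_accuracy(_points([(0.5, 1.5), (1.5, 1.5)]), cm, 3)
        assert res.fraction == 1.0

    def test_counting(self, make_grid):
        cm = self.classmap(make_grid)
        pts = _points([(0.5, 1.5), (1.5, 1.5), (0.5, 1.2), (0.5, 0.5)])
        res = overlay_accuracy(pts, cm, 3)
        assert res.fraction == 0.75
        assert res.counts == {3: 3, 1: 1}

    def test_susceptible_and_offgrid_points_dropped(self, make_grid):
        cm = self.classmap(make_grid)
        pts = _points([(0.5, 1.5)]) + _points([(0.5, 0.5)], status="susceptible")
        pts += _points([(10.0, 10.0)])  # off-grid
        res = overlay_accuracy(pts, cm, 3)
        assert res.n_scored == 1 and res.n_dropped == 2
        assert res.fraction == 1.0

    def test_no_scorable_points_is_an_error(self, make_grid):
        cm = self.classmap(make_grid)
        with pytest.raises(ValueError, match="no scorable"):
            overlay_accuracy(_points([(50.0, 50.0)]), cm, 3)

    def test_uniform_scatter_converges_to_area_fraction(self, make_grid):
        """Random points over a map with high-class area f score ~ f."""
        rng0 = np.random.default_rng(0)
        codes = np.where(rng0.random((20, 20)) < 0.3, 3.0, 1.0)
        cm = make_grid(codes, origin=(0.0, 0.0), cellsize=1.0)
        f = np.mean(codes == 3.0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = _points(zip(rng.uniform(0, 20, 2000), rng.uniform(0, 20, 2000)))
            res = overlay_accuracy(pts, cm, 3)
            assert res.fraction == pytest.approx(f, abs=0.03)


class TestPointsCsv:
    def test_round_trip(self, tmp_path):
        pts = _points([(1.5, -3.5), (10.0, 4.0)]) + _points([(2.0, 2.0)], "susceptible")
        path = tmp_path / "pts.csv"
        write_points_csv(pts, path)
        assert read_points_csv(path) == pts

    def test_missing_column_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("lon,lat,year\n1,2,2019\n")
        with pytest.raises(ValueError, match="status"):
            read_points_csv(path)

    def test_coordinate_bounds(self):
        with pytest.raises(ValueError, match="lat"):
            ResistancePoint(0.0, 95.0, 2019, "resistant")
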