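"""Raster model: I/O round-trips, resampling, IDW, DEM derivatives."""

import numpy as np
import pytest

from vegdyn.grid import (Grid, GridStack, GridTransform, PointSamples,
                         align_resample, idw_interpolate, read_grid,
                         slope_aspect, write_grid)


class TestIO:
    @pytest.mark.parametrize("ext", ["tif", "csv"])
    def test_round_trip_preserves_values_mask_and_transform(self, tmp_path, rng, ext):
        values = rng.random((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 4] = True
        g = Grid(values, GridTransform(5000.0, 42000.0, 250.0, 250.0), mask)
        path = str(tmp_path / f"g.{ext}")
        write_grid(g, path)
        back = read_grid(path)
        assert back.transform == g.transform
        assert np.array_equal(back.nodata_mask, mask)
        ok = ~mask
        assert np.max(np.abs(back.values[ok] - values[ok])) <= 1e-6

    def test_integer_raster_round_trip_is_exact(self, tmp_path):
        vals = np.arange(9, dtype=np.int32).reshape(3, 3)
        g = Grid(vals, GridTransform(0, 3, 1, 1))
        path = str(tmp_path / "int.tif")
        write_grid(g, path)
        assert np.array_equal(read_grid(path).values, vals)

    def test_nodata_cells_read_back_masked(self, tmp_path):
        vals = np.array([[1.0, -9999.0], [3.0, 4.0]])
        g = Grid(vals, GridTransform(0, 2, 1, 1), vals == -9999.0)
        path = str(tmp_path / "nd.tif")
        write_grid(g, path)
        assert read_grid(path).nodata_mask[0, 1]

    def test_csv_dialect_values(self, tmp_path):
        g = Grid([[1.0, 2.0], [3.0, 4.0]], GridTransform(0, 2, 1, 1))
        path = str(tmp_path / "g.csv")
        write_grid(g, path)
        assert np.array_equal(read_grid(path).values, [[1, 2], [3, 4]])

    def test_missing_file_and_missing_geotags_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_grid(str(tmp_path / "absent.tif"))
        import tifffile
        bare = str(tmp_path / "bare.tif")
        tifffile.imwrite(bare, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="geotransform"):
            read_grid(bare)


class TestStack:
    def test_stack_rejects_mismatched_geometry_and_unordered_times(self):
        a = Grid(np.zeros((2, 2)), GridTransform(0, 2, 1, 1))
        b = Grid(np.zeros((3, 2)), GridTransform(0, 3, 1, 1))
        with pytest.raises(ValueError, match="share shape"):
            GridStack([a, b], [(2001,), (2002,)])
        with pytest.raises(ValueError, match="increasing"):
            GridStack([a, a], [(2002,), (2001,)])


class TestResample:
    def test_identity_geometry_returns_same_values(self, grid_factory, rng):
        g = grid_factory(rng.random((5, 5)))
        for method in ("nearest", "bilinear"):
            out = align_resample(g, g, method)
            assert np.allclose(out.values, g.values)

    def test_bilinear_midpoint_between_rows(self):
        g = Grid([[0.0, 0.0], [10.0, 10.0]], GridTransform(0, 2, 1, 1))
        # target: single cell whose center sits midway between the two rows
        target = ((1, 2), GridTransform(0.0, 1.5, 1.0, 1.0))
        out = align_resample(g, target, "bilinear")
        assert np.allclose(out.values, 5.0)

    def test_bilinear_stays_within_source_range(self, grid_factory, rng):
        src = grid_factory(rng.random((8, 8)), cell=2.0)
        target = ((11, 11), GridTransform(0.5, 15.5, 1.4, 1.4))
        out = align_resample(src, target, "bilinear")
        ok = ~out.nodata_mask
        assert out.values[ok].min() >= src.values.min() - 1e-12
        assert out.values[ok].max() <= src.values.max() + 1e-12

    def test_nearest_never_invents_labels(self, grid_factory, rng):
        src = grid_factory(rng.integers(1, 5, (6, 6)).astype(float), cell=3.0)
        target = ((10, 10), GridTransform(0.0, 18.0, 1.8, 1.8))
        out = align_resample(src, target, "nearest")
        assert set(np.unique(out.values)) <= set(np.unique(src.values))

    def test_categorical_refuses_bilinear_and_overlap_required(self, grid_factory):
        g = grid_factory(np.ones((4, 4)))
        with pytest.raises(ValueError, match="categorical"):
            align_resample(g, g, "bilinear", categorical=True)
        far = ((4, 4), GridTransform(1e6, 1e6, 1.0, 1.0))
        with pytest.raises(ValueError, match="overlap"):
            align_resample(g, far, "nearest")


class TestIDW:
    def test_single_sample_gives_constant_grid(self):
        s = PointSamples([5.0], [5.0], [7.5])
        out = idw_interpolate(s, ((4, 4), GridTransform(0, 4, 1, 1)))
        assert np.allclose(out.values, 7.5)

    def test_equidistant_pair_averages(self):
        # cell center (1.0, 1.0); samples symmetric about it
        s = PointSamples([0.0, 2.0], [1.0, 1.0], [0.0, 10.0])
        out = idw_interpolate(s, ((1, 1), GridTransform(0.5, 1.5, 1.0, 1.0)))
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_weight_arithmetic_distances_1_and_3(self):
        # cell center (0.5, 0.5); samples at distance 1 and 3 on the x axis
        s = PointSamples([1.5, 3.5], [0.5, 0.5], [0.0, 10.0])
        out = idw_interpolate(s, ((1, 1), GridTransform(0.0, 1.0, 1.0, 1.0)),
                              power=2.0)
        expected = (0.0 * 1.0 + 10.0 * (1 / 9)) / (1.0 + 1 / 9)
        assert out.values[0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(1.0)

    @pytest.mark.parametrize("power", [0.5, 1.0, 2.0, 3.7])
    def test_reproduces_sample_values_at_sample_locations(self, rng, power):
        n = 12
        xs = rng.uniform(0, 8, n)
        ys = rng.uniform(0, 8, n)
        vals = rng.normal(size=n)
        # put one sample exactly on a cell center
        xs[0], ys[0] = 2.5, 3.5
        s = PointSamples(xs, ys, vals)
        out = idw_interpolate(s, ((8, 8), GridTransform(0, 8, 1, 1)), power=power)
        row, col = 4, 2                     # center (2.5, 3.5)
        assert out.values[row, col] == pytest.approx(vals[0], abs=1e-12)


class TestSlopeAspect:
    def test_flat_dem_slope_zero_aspect_flagged(self, grid_factory):
        slope, aspect = slope_aspect(grid_factory(np.full((5, 5), 1000.0)))
        assert np.allclose(slope.values, 0.0)
        assert np.all(aspect.values == -1.0)

    def test_east_rising_plane_is_45_degrees(self):
        cols = np.arange(7, dtype=float)
        dem = Grid(np.tile(cols, (7, 1)), GridTransform(0, 7, 1, 1))
        slope, aspect = slope_aspect(dem)
        interior = slope.values[1:-1, 1:-1]
        assert np.allclose(interior, 45.0, atol=1e-9)
        # surface faces west (270): downhill is -x
        assert np.allclose(aspect.values[1:-1, 1:-1], 270.0, atol=1e-9)

    def test_south_rising_plane_faces_north(self):
        rows = np.arange(6, dtype=float)[:, None]     # higher toward south
        dem = Grid(np.tile(rows, (1, 6)), GridTransform(0, 6, 1, 1))
        _, aspect = slope_aspect(dem)
        assert np.allclose(aspect.values[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_any_plane_constant_in_interior(self, rng):
        for _ in range(5):
            a, b = rng.uniform(-2, 2, 2)
            rr, cc = np.meshgrid(np.arange(9.0), np.arange(9.0), indexing="ij")
            dem = Grid(a * cc + b * rr, GridTransform(0, 9, 1, 1))
            slope, aspect = slope_aspect(dem, flat_threshold=0.0)
            interior_s = slope.values[1:-1, 1:-1]
            assert np.ptp(interior_s) < 1e-6
            if interior_s.max() > 1e-9:
                ia = aspect.values[1:-1, 1:-1]
                assert np.ptp(ia) < 1e-6

    def test_too_small_dem_rejected(self, grid_factory):
        with pytest.raises(ValueError, match="3x3"):
            slope_aspect(grid_factory(np.zeros((2, 5))))
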