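"""Resampling, terrain derivatives and summaries against analytic oracles."""

import numpy as np
import pytest

from habitatrf.raster import EnvironmentalStack, GridGeometry, RasterGrid
from habitatrf.raster_ops import (
    METRES_PER_DEGREE,
    aggregate_block_mean,
    aspect,
    harmonize,
    hillshade,
    layer_summary,
    resample_bilinear,
    slope,
)


def horn_oracle(z: np.ndarray, dx: float, dy: float, i: int, j: int):
    """Literal per-cell Horn stencil with replicated edges -> (dzdx, dzdy)."""
    nr, nc = z.shape

    def at(r, c):
        return z[min(max(r, 0), nr - 1), min(max(c, 0), nc - 1)]

    a, b, c_ = at(i - 1, j - 1), at(i - 1, j), at(i - 1, j + 1)
    d, f = at(i, j - 1), at(i, j + 1)
    g, h, k = at(i + 1, j - 1), at(i + 1, j), at(i + 1, j + 1)
    dzdx = ((c_ + 2 * f + k) - (a + 2 * d + g)) / (8 * dx)
    dzdy = ((a + 2 * b + c_) - (g + 2 * h + k)) / (8 * dy)
    return dzdx, dzdy


class TestResampleBilinear:
    def test_constant_preserved(self, unit_geom):
        src = RasterGrid(np.full(unit_geom.shape, 7.0), unit_geom)
        target = GridGeometry(1.3, 8.7, 0.7, 0.7, 5, 5)
        out = resample_bilinear(src, target)
        np.testing.assert_allclose(out.values, 7.0)

    def test_centre_of_2x2_is_equal_weight_mean(self):
        geom = GridGeometry(0, 2, 1.0, 1.0, 2, 2)
        src = RasterGrid(np.array([[0.0, 2.0], [4.0, 6.0]]), geom)
        # single target cell whose centre coincides with the 4-centre centroid
        target = GridGeometry(0.5, 1.5, 1.0, 1.0, 1, 1)
        assert resample_bilinear(src, target).values[0, 0] == pytest.approx(3.0)

    def test_reproduces_affine_surface_exactly(self):
        geom = GridGeometry(0, 20, 1.0, 1.0, 20, 20)
        jj, ii = np.meshgrid(np.arange(20), np.arange(20))
        x, y = geom.cell_center(ii, jj)
        src = RasterGrid(2 * x + 3 * y, geom)
        target = GridGeometry(4.0, 16.0, 0.3, 0.3, 30, 30)  # interior
        out = resample_bilinear(src, target)
        tj, ti = np.meshgrid(np.arange(30), np.arange(30))
        tx, ty = target.cell_center(ti, tj)
        np.testing.assert_allclose(out.values, 2 * tx + 3 * ty, atol=1e-9)

    def test_identity_on_own_grid(self, small_stack):
        grid = small_stack["temp"]
        out = resample_bilinear(grid, grid.geometry)
        np.testing.assert_allclose(out.values, grid.values, atol=1e-12)

    def test_no_overshoot(self, unit_geom):
        rng = np.random.default_rng(0)
        src = RasterGrid(rng.uniform(-3, 9, unit_geom.shape), unit_geom)
        target = GridGeometry(-2.0, 12.0, 0.37, 0.37, 40, 40)  # spills past edges
        out = resample_bilinear(src, target)
        assert out.values.min() >= src.values.min() - 1e-12
        assert out.values.max() <= src.values.max() + 1e-12

    def test_nodata_stencil_propagates(self, unit_geom):
        v = np.full(unit_geom.shape, -9999.0)
        v[:2, :2] = 5.0
        src = RasterGrid(v, unit_geom)
        out = resample_bilinear(src, unit_geom)
        assert out.values[0, 0] == 5.0
        assert out.values[9, 9] == -9999.0

    def test_disjoint_extents_rejected(self, unit_geom):
        src = RasterGrid(np.zeros(unit_geom.shape), unit_geom)
        far = GridGeometry(100.0, 10.0, 1.0, 1.0, 10, 10)
        with pytest.raises(ValueError, match="disjoint"):
            resample_bilinear(src, far)

    def test_block_mean_matches_manual_blocks(self):
        geom = GridGeometry(0, 4, 1.0, 1.0, 4, 4)
        v = np.arange(16, dtype=float).reshape(4, 4)
        target = GridGeometry(0, 4, 2.0, 2.0, 2, 2)
        out = aggregate_block_mean(RasterGrid(v, geom), target)
        expected = np.array([[v[:2, :2].mean(), v[:2, 2:].mean()],
                             [v[2:, :2].mean(), v[2:, 2:].mean()]])
        np.testing.assert_allclose(out.values, expected)

    def test_harmonize_targets_coarsest_layer(self, tiny_landscape):
        from habitatrf.synthetic import LayerSpec, generate_environment

        tiny_landscape.resolutions = {"env": 1 / 40, "fine": 1 / 80}
        specs = dict(tiny_landscape.layer_specs)
        specs["fine_layer"] = LayerSpec("fine", 0.0, 1.0, 0.05)
        tiny_landscape.layer_specs = specs
        stack = generate_environment(tiny_landscape)
        assert not stack.harmonized
        harm = harmonize(stack)
        assert harm.harmonized
        assert harm.geometry.dx == 1 / 40


class TestTerrain:
    def _planar_dem(self, values):
        nr, nc = values.shape
        geom = GridGeometry(0, nr * 1.0, 1.0, 1.0, nr, nc)
        return RasterGrid(np.asarray(values, dtype=float), geom)

    def test_flat_dem_slope_zero_hillshade_255(self):
        dem = self._planar_dem(np.full((5, 5), 100.0))
        assert np.all(slope(dem, geographic=False).values == 0.0)
        hs = hillshade(dem, sun_altitude=90.0, geographic=False)
        assert np.all(hs.values == 255.0)

    def test_flat_aspect_is_nodata(self):
        dem = self._planar_dem(np.full((5, 5), 100.0))
        asp = aspect(dem, geographic=False)
        assert not asp.valid_mask.any()

    def test_east_dipping_plane(self):
        # z falls eastward at tan(10 deg) per unit: slope 10 deg, aspect 90 deg
        x = np.arange(8) * 1.0
        z = -np.tan(np.radians(10.0)) * x
        dem = self._planar_dem(np.tile(z, (8, 1)))
        s = slope(dem, geographic=False)
        a = aspect(dem, geographic=False)
        np.testing.assert_allclose(s.values[2:-2, 2:-2], 10.0, atol=1e-6)
        np.testing.assert_allclose(a.values[2:-2, 2:-2], 90.0, atol=1e-6)

    def test_north_dipping_plane_aspect_zero_not_360(self):
        y = np.arange(8) * 1.0
        dem = self._planar_dem(np.tile((y * 0.2)[:, None], (1, 8)))  # falls northward
        a = aspect(dem, geographic=False)
        np.testing.assert_allclose(a.values[2:-2, 2:-2], 0.0, atol=1e-12)

    def test_matches_per_cell_horn_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(0, 50, (10, 10))
        dem = self._planar_dem(z)
        s = slope(dem, geographic=False).values
        a = aspect(dem, geographic=False).values
        for i in range(10):
            for j in range(10):
                dzdx, dzdy = horn_oracle(z, 1.0, 1.0, i, j)
                assert s[i, j] == pytest.approx(
                    np.degrees(np.arctan(np.hypot(dzdx, dzdy))), abs=1e-9
                )
                assert a[i, j] == pytest.approx(
                    np.degrees(np.arctan2(-dzdx, -dzdy)) % 360, abs=1e-9
                )

    def test_geographic_mode_scales_by_metres_per_degree(self):
        # 0.01 deg cells: a rise of tan(10)*0.01*111320*cos(lat) per cell eastward
        geom = GridGeometry(30.0, 0.005 * 8, 0.01, 0.01, 8, 8)
        lat = geom.row_center_latitudes()[4]
        dx_m = 0.01 * METRES_PER_DEGREE * np.cos(np.radians(lat))
        x = np.arange(8) * dx_m
        dem = RasterGrid(np.tile(-np.tan(np.radians(10.0)) * x, (8, 1)), geom)
        s = slope(dem, geographic=True)
        assert s.values[4, 4] == pytest.approx(10.0, abs=1e-3)

    def test_small_dem_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            slope(self._planar_dem(np.zeros((2, 5))), geographic=False)

    def test_edge_policy_nodata_masks_border(self):
        dem = self._planar_dem(np.random.default_rng(1).uniform(0, 5, (6, 6)))
        s = slope(dem, geographic=False, edge_policy="nodata")
        assert not s.valid_mask[0].any() and not s.valid_mask[-1].any()
        assert s.valid_mask[1:-1, 1:-1].all()


class TestLayerSummary:
    def test_constant_layer_all_statistics_equal(self, unit_geom):
        stack = EnvironmentalStack({"c": RasterGrid(np.ones(unit_geom.shape), unit_geom)})
        row = layer_summary(stack).loc["c"]
        assert set(row) == {1.0}

    def test_small_known_values(self):
        geom = GridGeometry(0, 1, 1.0, 1.0, 1, 5)
        stack = EnvironmentalStack(
            {"v": RasterGrid(np.array([[1.0, 2, 3, 4, 5]]), geom)}
        )
        row = layer_summary(stack).loc["v"]
        assert row["median"] == 3.0 and row["mean"] == 3.0
        assert row["min"] == 1.0 and row["max"] == 5.0

    def test_uniform_quartiles_near_theory(self):
        geom = GridGeometry(0, 100, 1.0, 1.0, 100, 100)
        vals = np.random.default_rng(9).uniform(0, 1, (100, 100))
        stack = EnvironmentalStack({"u": RasterGrid(vals, geom)})
        row = layer_summary(stack).loc["u"]
        # sorting oracle agreement at n = 10,000
        assert abs(row["q1"] - 0.25) < 0.02
        assert abs(row["median"] - 0.5) < 0.02
        assert abs(row["q3"] - 0.75) < 0.02
        assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]

    def test_all_nodata_layer_rejected(self, unit_geom):
        stack = EnvironmentalStack(
            {"x": RasterGrid(np.full(unit_geom.shape, -9999.0), unit_geom)}
        )
        with pytest.raises(ValueError, match="zero valid"):
            layer_summary(stack)
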