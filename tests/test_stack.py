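import numpy as np
import pytest
from shapely.geometry import box

from esdm.grid import GridError, RasterGrid
from esdm.stack import (FLAT_ASPECT, AlignmentError, PredictorStack, align,
                        cover_fractions, distance_raster, gcm_mean, terrain,
                        vif_screen)
from esdm.synthetic import LandscapeSpec, make_stack

from conftest import constant_grid, stack_from_arrays


class TestAlign:
    def test_layer_already_on_template_is_value_identical(self, template):
        layer = template.with_values(np.arange(100, dtype=float).reshape(10, 10))
        out = align({"x": layer}, template)
        np.testing.assert_array_equal(out["x"].values, layer.values)

    def test_constant_layer_stays_constant(self, template):
        src = RasterGrid(np.full((20, 20), 7.0), 0.0, 10.0, 0.5)
        out = align({"x": src}, template)
        np.testing.assert_allclose(out["x"].values[1:-1, 1:-1], 7.0)

    def test_downsampled_ramp_matches_analytic_values(self):
        # source: 1-km cells holding a linear ramp in x; template: 2-km cells.
        # bilinear resampling must reproduce the ramp at the new cell centres.
        src_vals = np.tile(np.arange(20, dtype=float), (20, 1))  # value = col
        src = RasterGrid(src_vals, 0.0, 20.0, 1.0)
        template = RasterGrid(np.zeros((10, 10)), 0.0, 20.0, 2.0)
        out = align({"ramp": src}, template)
        # template col j centre x = 2j+1 -> source fractional col (x-0.5)
        expected = np.tile(2.0 * np.arange(10) + 0.5, (10, 1))
        np.testing.assert_allclose(out["ramp"].values[1:-1, 1:-1],
                                   expected[1:-1, 1:-1], rtol=1e-12)

    def test_non_overlapping_extent_rejected(self, template):
        far = RasterGrid(np.zeros((5, 5)), 100.0, 105.0, 1.0)
        with pytest.raises(AlignmentError):
            align({"x": far}, template)


class TestTerrain:
    def test_flat_dem_zero_slope_flat_aspect(self):
        dem = constant_grid(100.0, shape=(8, 8))
        t = terrain(dem)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(t["slope"].values[interior], 0.0)
        np.testing.assert_allclose(t["aspect"].values[interior], FLAT_ASPECT)

    def test_unit_plane_in_x_gives_45_degrees_facing_west(self):
        x = np.tile(np.arange(8, dtype=float), (8, 1))  # z = x, 1 km cells
        dem = RasterGrid(x, 0.0, 8.0, 1.0)
        t = terrain(dem)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(t["slope"].values[interior], 45.0)
        np.testing.assert_allclose(t["aspect"].values[interior], 270.0)

    def test_plane_rising_north_faces_south(self):
        # z = y: downslope bearing is due south (180 degrees)
        y = np.tile(np.arange(8, 0, -1, dtype=float)[:, None], (1, 8))
        dem = RasterGrid(y, 0.0, 8.0, 1.0)
        t = terrain(dem)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(t["aspect"].values[interior], 180.0)
        np.testing.assert_allclose(t["slope"].values[interior], 45.0)

    def test_too_small_dem_rejected(self):
        with pytest.raises(GridError):
            terrain(RasterGrid(np.zeros((1, 8)), 0.0, 1.0, 1.0))


class TestDistance:
    def test_cell_containing_feature_is_zero(self, template):
        d = distance_raster(np.array([[2.3, 7.1]]), template)
        row, col = template.index_of(2.3, 7.1)
        assert d.values[row, col] == 0.0

    def test_single_feature_distance_is_euclidean(self, template):
        d = distance_raster(np.array([[0.0, 10.0]]), template)  # top-left corner
        X, Y = template.centre_grids()
        expected = np.hypot(X - 0.0, Y - 10.0)
        # half-cell tolerance except the containing cell (forced to 0)
        diff = np.abs(d.values - expected)
        diff[0, 0] = 0.0
        assert diff.max() <= 0.5 * np.sqrt(2) + 1e-12

    def test_two_features_take_pointwise_minimum(self, template):
        f1, f2 = np.array([[1.2, 3.4]]), np.array([[8.8, 9.1]])
        d1 = distance_raster(f1, template)
        d2 = distance_raster(f2, template)
        both = distance_raster(np.vstack([f1, f2]), template)
        np.testing.assert_allclose(both.values,
                                   np.minimum(d1.values, d2.values))

    def test_adding_features_never_increases_distance(self, template):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(6, 2))
        d_few = distance_raster(pts[:3], template)
        d_all = distance_raster(pts, template)
        assert (d_all.values <= d_few.values + 1e-12).all()

    def test_polygon_features_zero_inside(self, template):
        poly = box(2.0, 2.0, 5.0, 5.0)
        d = distance_raster([poly], template)
        row, col = template.index_of(3.5, 3.5)
        assert d.values[row, col] == 0.0
        row, col = template.index_of(9.5, 9.5)
        assert d.values[row, col] == pytest.approx(np.hypot(4.5, 4.5))

    def test_empty_feature_set_rejected(self, template):
        with pytest.raises(ValueError):
            distance_raster(np.empty((0, 2)), template)


class TestVif:
    def test_orthogonal_layers_none_dropped(self):
        spec = LandscapeSpec(extent=(0, 0, 100, 100), n_predictors=4, seed=2)
        report, reduced = vif_screen(make_stack(spec), seed=0)
        assert report.steps == []
        assert len(reduced) == 4
        assert all(v < 1.05 for v in report.retained.values())

    def test_duplicated_layer_dropped_first(self, stack_100):
        dup = stack_100.with_layer("env01_copy", stack_100["env01"])
        report, reduced = vif_screen(dup, seed=0)
        assert report.steps[0][0] == "env01_copy"  # lexicographically later
        assert report.steps[0][1] == np.inf
        assert "env01" in reduced.names

    def test_rho_09_pair_matches_closed_form_and_one_drop(self, stack_100):
        # engineered pair at rho = 0.9: VIF = 1/(1-0.81) ~ 5.263, over the
        # threshold, so exactly one of the pair is dropped
        report, reduced = vif_screen(stack_100, threshold=5.0, seed=0)
        assert len(report.steps) == 1
        dropped, vif_at_drop = report.steps[0]
        assert dropped in ("env01", "env02")
        assert abs(vif_at_drop - 1 / (1 - 0.81)) / (1 / (1 - 0.81)) < 0.05
        assert all(v < 5.0 for v in report.retained.values())

    def test_screen_terminates_and_partitions_names(self, stack_100):
        report, reduced = vif_screen(stack_100, seed=0)
        assert len(report.steps) <= len(stack_100) - 1
        assert sorted(report.dropped + list(report.retained)) == sorted(stack_100.names)

    def test_single_layer_stack_rejected(self, template):
        s = PredictorStack({"only": template.with_values(np.random.default_rng(0)
                                                         .normal(size=(10, 10)))})
        with pytest.raises(ValueError):
            vif_screen(s)


class TestGcmMean:
    def test_identical_members_mean_is_member(self, stack_100):
        out = gcm_mean([stack_100] * 5)
        for n in stack_100.names:
            np.testing.assert_allclose(out[n].values, stack_100[n].values)

    def test_constant_members_average(self):
        stacks = [stack_from_arrays(a=np.full((4, 4), float(k)))
                  for k in range(1, 6)]
        out = gcm_mean(stacks)
        np.testing.assert_allclose(out["a"].values, 3.0)

    def test_mean_matches_cellwise_recomputation_and_permutation(self):
        rng = np.random.default_rng(3)
        stacks = [stack_from_arrays(a=rng.normal(size=(5, 5)),
                                    b=rng.normal(size=(5, 5))) for _ in range(4)]
        out = gcm_mean(stacks)
        expected = np.mean([s["a"].values for s in stacks], axis=0)
        np.testing.assert_allclose(out["a"].values, expected)
        out_perm = gcm_mean(stacks[::-1])
        for n in ("a", "b"):
            np.testing.assert_allclose(out_perm[n].values, out[n].values)

    def test_nodata_propagates(self):
        a1 = np.ones((3, 3))
        a2 = np.ones((3, 3))
        a2[1, 1] = np.nan
        out = gcm_mean([stack_from_arrays(a=a1), stack_from_arrays(a=a2)])
        assert np.isnan(out["a"].values[1, 1])

    def test_mismatched_names_rejected(self):
        with pytest.raises(ValueError):
            gcm_mean([stack_from_arrays(a=np.ones((3, 3))),
                      stack_from_arrays(b=np.ones((3, 3)))])


def test_cover_fractions_by_block_aggregation():
    cat = np.zeros((4, 4))
    cat[:2, :2] = 1.0  # one full block of class 1
    cat[2, 2] = 1.0    # quarter of another block
    grid = RasterGrid(cat, 0.0, 4.0, 1.0)
    frac = cover_fractions(grid, classes=[1], block=2)["frac_1"]
    np.testing.assert_allclose(frac.values, [[1.0, 0.0], [0.0, 0.25]])
    assert frac.cell_size == 2.0
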