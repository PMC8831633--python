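import numpy as np
import pytest
from scipy.stats import spearmanr

import climstab as cs


class TestNormalize01:
    def test_three_values_span_unit_interval(self, grid):
        vals = np.full(grid.shape, 4.0, dtype=np.float32)
        vals[0, 0], vals[0, 1], vals[0, 2] = 2.0, 4.0, 6.0
        out = cs.normalize01(cs.RasterLayer(grid, vals, variable_id="x"))
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == 0.5
        assert out.values[0, 2] == 1.0

    def test_constant_layer_warns_and_zeroes(self, make_layer):
        with pytest.warns(UserWarning, match="constant"):
            out = cs.normalize01(make_layer(7.0))
        assert np.all(out.valid_values() == 0.0)

    def test_all_nodata_rejected(self, grid):
        layer = cs.RasterLayer(grid, np.full(grid.shape, np.nan),
                               variable_id="x")
        with pytest.raises(ValueError):
            cs.normalize01(layer)

    def test_rank_order_preserved(self, grid, rng):
        vals = rng.normal(size=grid.shape)
        vals[rng.random(grid.shape) < 0.2] = np.nan
        layer = cs.RasterLayer(grid, vals, variable_id="x")
        out = cs.normalize01(layer)
        ok = layer.valid_mask
        rho = spearmanr(layer.values[ok], out.values[ok]).statistic
        assert rho == pytest.approx(1.0)
        assert np.nanmin(out.values) == 0.0
        assert np.nanmax(out.values) == 1.0
        assert np.array_equal(out.valid_mask, ok)


class TestComposeCSI:
    def norm_layers(self, grid, rng, n=3):
        layers = {}
        for i in range(n):
            vals = rng.random(grid.shape)
            layer = cs.RasterLayer(grid, vals, variable_id=f"v{i}")
            layers[f"v{i}"] = cs.normalize01(layer)
        return layers

    def test_single_variable_is_renormalized_identity(self, grid, rng):
        layers = self.norm_layers(grid, rng, 1)
        result = cs.compose_csi(layers, ["v0"])
        assert np.allclose(result.csi.values, layers["v0"].values,
                           atol=1e-6)

    def test_order_of_kept_list_is_irrelevant(self, grid, rng):
        layers = self.norm_layers(grid, rng, 3)
        a = cs.compose_csi(layers, ["v0", "v1", "v2"])
        b = cs.compose_csi(layers, ["v2", "v0", "v1"])
        assert np.array_equal(a.csi.values, b.csi.values)

    def test_matches_sum_then_normalize_oracle(self, grid, rng):
        layers = self.norm_layers(grid, rng, 3)
        result = cs.compose_csi(layers, ["v0", "v1", "v2"])
        total = sum(layers[k].values.astype(float)
                    for k in ("v0", "v1", "v2"))
        expected = (total - total.min()) / (total.max() - total.min())
        assert np.allclose(result.csi.values, expected, atol=1e-6)

    def test_empty_kept_list_rejected(self, grid, rng):
        with pytest.raises(ValueError, match="empty"):
            cs.compose_csi(self.norm_layers(grid, rng), [])

    def test_nodata_propagation_is_strict(self, grid, rng):
        layers = self.norm_layers(grid, rng, 2)
        layers["v0"].values[3, 3] = np.nan
        result = cs.compose_csi(layers, ["v0", "v1"])
        assert np.isnan(result.csi.values[3, 3])

    def test_affine_rescaling_of_raw_input_changes_nothing(self,
                                                           make_stack):
        """Per-variable normalization makes the index invariant to a
        variable's units: x10 on a raw stack is a no-op downstream."""
        rng = np.random.default_rng(5)
        grid = cs.Grid.regular(10, 12, origin=(0.0, 10.0),
                               resolution=0.1)
        per_period = [rng.normal(size=grid.shape) for _ in range(6)]
        base = make_stack(per_period)
        scaled = cs.RasterStack.from_layers(
            [l.with_values(l.values * 10.0) for l in base.layers])
        out = {}
        for tag, stack in (("base", base), ("scaled", scaled)):
            norm = cs.normalize01(cs.pixelwise_sd(stack))
            norm.variable_id = "bio1"
            out[tag] = cs.compose_csi({"bio1": norm}, ["bio1"]).csi
        assert np.allclose(out["base"].values, out["scaled"].values,
                           atol=1e-6)


class TestBreakScheme:
    def test_equal_interval_breaks(self):
        scheme = cs.BreakScheme.equal_interval(4)
        assert scheme.breaks == (0.25, 0.5, 0.75, 1.0)

    def test_breaks_must_ascend_and_end_at_one(self):
        with pytest.raises(ValueError):
            cs.BreakScheme((0.5, 0.4, 1.0))
        with pytest.raises(ValueError):
            cs.BreakScheme((0.2, 0.9))

    def test_top_weighted_scheme(self):
        scheme = cs.BreakScheme.with_top_break(32, 0.71)
        assert scheme.n_categories == 32
        assert scheme.breaks[-2] == pytest.approx(0.71)
        assert scheme.breaks[-1] == 1.0


class TestCategorize:
    def test_past_style_top_category(self, make_layer):
        """0.80 lands in the top category of a 32-class scheme whose
        uppermost bin spans 0.71-1."""
        scheme = cs.BreakScheme.with_top_break(32, 0.71)
        out = cs.categorize(make_layer(0.80), scheme)
        assert np.all(out.valid_values() == 32)

    def test_future_style_top_category(self, make_layer):
        """0.40 lands in the top category when the uppermost bin spans
        0.356-1."""
        scheme = cs.BreakScheme.with_top_break(32, 0.356)
        out = cs.categorize(make_layer(0.40), scheme)
        assert np.all(out.valid_values() == 32)

    def test_zero_maps_to_first_category(self, make_layer):
        scheme = cs.BreakScheme.equal_interval(32)
        out = cs.categorize(make_layer(0.0), scheme)
        assert np.all(out.valid_values() == 1)

    def test_bins_are_upper_inclusive(self, make_layer):
        scheme = cs.BreakScheme((0.5, 1.0))
        assert np.all(cs.categorize(make_layer(0.5),
                                    scheme).valid_values() == 1)
        assert np.all(cs.categorize(make_layer(0.51),
                                    scheme).valid_values() == 2)

    def test_out_of_range_rejected(self, make_layer):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            cs.categorize(make_layer(1.5), cs.BreakScheme.equal_interval(4))

    def test_valid_pixels_stay_valid_through_normalize(self, grid, rng):
        vals = rng.normal(size=grid.shape)
        vals[rng.random(grid.shape) < 0.3] = np.nan
        layer = cs.RasterLayer(grid, vals, variable_id="x")
        out = cs.categorize(cs.normalize01(layer),
                            cs.BreakScheme.equal_interval(32))
        assert np.array_equal(out.valid_mask, layer.valid_mask)


class TestHistogram:
    def test_point_mass_fills_one_bin(self, make_layer):
        hist = cs.histogram(make_layer(0.5), 10)
        assert len(hist) == 10
        assert hist["count"].sum() == make_layer(0.5).values.size
        assert (hist["count"] > 0).sum() == 1

    def test_counts_sum_to_valid_pixels(self, grid, rng):
        vals = rng.random(grid.shape)
        vals[rng.random(grid.shape) < 0.4] = np.nan
        layer = cs.RasterLayer(grid, vals, variable_id="x")
        hist = cs.histogram(layer, 17)
        assert hist["count"].sum() == layer.n_valid

    def test_empty_bins_reported_as_zero(self, make_layer):
        hist = cs.histogram(make_layer(0.0), 5)
        assert len(hist) == 5
        assert list(hist["count"])[1:] == [0, 0, 0, 0]

    def test_invalid_bin_count(self, make_layer):
        with pytest.raises(ValueError):
            cs.histogram(make_layer(0.5), 0)
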