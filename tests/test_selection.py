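import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import climstab as cs
from climstab.errors import ConstantLayerError, InsufficientPixelsError


def pearson_oracle(x, y):
    """Textbook Pearson r from first principles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum()
                 / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def random_corr_matrix(rng, n):
    """Random valid correlation matrix via a Gram construction."""
    a = rng.normal(size=(n, n + 2))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    import pandas as pd
    names = [f"v{i}" for i in range(n)]
    return pd.DataFrame(c, index=names, columns=names)


class TestSamplePoints:
    def test_deterministic_per_seed(self, grid):
        mask = cs.MaskLayer(grid, np.ones(grid.shape))
        a = cs.sample_points(mask, 50, seed=3)
        b = cs.sample_points(mask, 50, seed=3)
        assert np.array_equal(a, b)
        c = cs.sample_points(mask, 50, seed=4)
        assert not np.array_equal(a, c)

    def test_exhaustive_sample_covers_every_valid_pixel(self, grid, rng):
        keep = (rng.random(grid.shape) < 0.5).astype(float)
        mask = cs.MaskLayer(grid, keep)
        n = int(keep.sum())
        pts = cs.sample_points(mask, n, seed=0)
        assert len(np.unique(pts, axis=0)) == n

    def test_all_points_land_on_valid_pixels(self, grid, rng):
        keep = (rng.random(grid.shape) < 0.5).astype(float)
        mask = cs.MaskLayer(grid, keep)
        pts = cs.sample_points(mask, 20, seed=1)
        assert np.all(keep[pts[:, 0], pts[:, 1]] == 1.0)

    def test_insufficient_pixels_error_not_silent_reduction(self, grid):
        mask = cs.MaskLayer(grid, np.zeros(grid.shape))
        with pytest.raises(InsufficientPixelsError):
            cs.sample_points(mask, 10, seed=0)


class TestCorrelationMatrix:
    def layer_pair(self, grid, rng):
        x = rng.normal(size=grid.shape)
        a = cs.RasterLayer(grid, x, variable_id="a")
        b = cs.RasterLayer(grid, -x, variable_id="b")
        return a, b

    def test_self_and_negation(self, grid, rng):
        a, b = self.layer_pair(grid, rng)
        pts = np.array([[i, j] for i in range(grid.n_rows)
                        for j in range(grid.n_cols)])
        corr = cs.correlation_matrix([a, b], pts)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(corr.values, corr.values.T, atol=1e-12)

    def test_five_point_toy_matches_textbook_formula(self, rng):
        grid = cs.Grid.regular(1, 5, resolution=0.5)
        xv = np.array([[1.0, 2.0, 4.0, 4.5, 7.0]])
        yv = np.array([[2.0, 1.0, 5.0, 3.0, 9.0]])
        a = cs.RasterLayer(grid, xv, variable_id="a")
        b = cs.RasterLayer(grid, yv, variable_id="b")
        pts = np.array([[0, j] for j in range(5)])
        corr = cs.correlation_matrix([a, b], pts)
        assert corr.loc["a", "b"] == pytest.approx(
            pearson_oracle(xv[0], yv[0]), abs=1e-12)

    def test_pairwise_deletion_of_nodata_points(self, grid, rng):
        a, b = self.layer_pair(grid, rng)
        b.values[0, 0] = np.nan
        pts = np.array([[0, j] for j in range(grid.n_cols)])
        corr = cs.correlation_matrix([a, b], pts)
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-9)

    def test_constant_layer_named_in_error(self, grid, rng):
        a, _ = self.layer_pair(grid, rng)
        flat = cs.RasterLayer(grid, np.full(grid.shape, 2.0),
                              variable_id="flatvar")
        pts = np.array([[0, j] for j in range(grid.n_cols)])
        with pytest.raises(ConstantLayerError, match="flatvar"):
            cs.correlation_matrix([a, flat], pts)


class TestCorrelatedGroups:
    def frame(self, entries, names=("A", "B", "C")):
        import pandas as pd
        m = np.eye(len(names))
        for (i, j), r in entries.items():
            m[i, j] = m[j, i] = r
        return pd.DataFrame(m, index=list(names), columns=list(names))

    def test_below_threshold_all_singletons(self):
        corr = self.frame({(0, 1): 0.5, (0, 2): -0.2, (1, 2): 0.7})
        assert cs.correlated_groups(corr, 0.8) == [["A"], ["B"], ["C"]]

    def test_all_exceeding_forms_one_group(self):
        corr = self.frame({(0, 1): 0.9, (0, 2): 0.95, (1, 2): -0.85})
        assert cs.correlated_groups(corr, 0.8) == [["A", "B", "C"]]

    def test_chain_closure_merges_transitively(self):
        corr = self.frame({(0, 1): 0.9, (1, 2): 0.9, (0, 2): 0.1})
        assert cs.correlated_groups(corr, 0.8) == [["A", "B", "C"]]

    def test_signed_mode_ignores_negative_links(self):
        corr = self.frame({(0, 1): -0.9})
        assert cs.correlated_groups(corr, 0.8) == [["A", "B"], ["C"]]
        assert cs.correlated_groups(corr, 0.8, use_absolute=False) == \
            [["A"], ["B"], ["C"]]

    @given(seed=st.integers(0, 10_000))
    def test_raising_threshold_refines_partition(self, seed):
        rng = np.random.default_rng(seed)
        corr = random_corr_matrix(rng, 8)
        coarse = cs.correlated_groups(corr, 0.7)
        fine = cs.correlated_groups(corr, 0.9)
        coarse_sets = [set(g) for g in coarse]
        for g in fine:
            assert any(set(g) <= cg for cg in coarse_sets)


class TestSelectVariables:
    def test_singletons_kept_verbatim(self):
        groups = [["a"], ["b"], ["c"]]
        assert cs.select_variables(groups, seed=0) == ["a", "b", "c"]

    def test_one_representative_per_group(self):
        groups = [["a", "b", "c"], ["d"]]
        kept = cs.select_variables(groups, seed=5)
        assert len(kept) == 2
        assert kept[0] in groups[0] and kept[1] == "d"

    def test_uniform_pick_frequency(self):
        group = [["w", "x", "y", "z"]]
        counts = {m: 0 for m in group[0]}
        for seed in range(10_000):
            counts[cs.select_variables(group, seed)[0]] += 1
        for m, c in counts.items():
            assert abs(c / 10_000 - 0.25) < 0.02, (m, c)

    def test_kept_count_equals_group_count(self, rng):
        corr = random_corr_matrix(rng, 10)
        for th in (0.3, 0.5, 0.8):
            groups = cs.correlated_groups(corr, th)
            assert len(cs.select_variables(groups, 1)) == len(groups)


class TestEndToEndSelection:
    def test_planted_blocks_recovered_exactly(self, past_world):
        mask = cs.build_land_mask(past_world.template)
        norm = {}
        for var, stack in past_world.stacks.items():
            sd = cs.apply_land_mask(cs.pixelwise_sd(stack), mask)
            sd.variable_id = var
            norm[var] = cs.normalize01(sd)
        layers = [norm[v] for v in sorted(
            norm, key=lambda s: int(s[3:]))]
        cfg = cs.SelectionConfig(n_points=1000, r_threshold=0.8,
                                 sampling_seed=11, selection_seed=12)
        result = cs.select_uncorrelated(layers, mask, cfg)
        assert result.groups == past_world.truth["expected_groups"]
        assert len(result.kept) == len(result.groups)

    def test_stable_under_fixed_seed(self, past_world):
        mask = cs.build_land_mask(past_world.template)
        stack = past_world.stacks["bio1"]
        other = past_world.stacks["bio4"]
        layers = []
        for var, st_ in (("bio1", stack), ("bio4", other)):
            sd = cs.apply_land_mask(cs.pixelwise_sd(st_), mask)
            sd.variable_id = var
            layers.append(cs.normalize01(sd))
        cfg = cs.SelectionConfig(n_points=500, sampling_seed=2,
                                 selection_seed=3)
        r1 = cs.select_uncorrelated(layers, mask, cfg)
        r2 = cs.select_uncorrelated(layers, mask, cfg)
        assert r1.kept == r2.kept
        assert np.array_equal(r1.sampled_points, r2.sampled_points)
        assert r1.corr_matrix.equals(r2.corr_matrix)

    def test_json_round_trip(self, past_world):
        mask = cs.build_land_mask(past_world.template)
        layers = []
        for var in ("bio1", "bio4"):
            sd = cs.apply_land_mask(
                cs.pixelwise_sd(past_world.stacks[var]), mask)
            sd.variable_id = var
            layers.append(cs.normalize01(sd))
        cfg = cs.SelectionConfig(n_points=200)
        result = cs.select_uncorrelated(layers, mask, cfg)
        back = cs.SelectionResult.from_json(result.to_json())
        assert back.kept == result.kept
        assert back.groups == result.groups
        assert np.allclose(back.corr_matrix.values,
                           result.corr_matrix.values)


class TestConfigValidation:
    def test_threshold_bounds(self):
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                cs.SelectionConfig(r_threshold=bad)

    def test_min_points(self):
        with pytest.raises(ValueError):
            cs.SelectionConfig(n_points=1)
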