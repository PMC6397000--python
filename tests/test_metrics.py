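"""Spatial coding metrics: stability, information, local stability,
field-position uniformity, map similarity."""

import numpy as np
import pytest

from placecode import BinGrid
from placecode.metrics import (local_stability, map_similarity,
                               mutual_information, mutual_information_z,
                               spatial_information, stability_index,
                               uniformity_test)
from placecode.ratemaps import firing_rate_map
from placecode.simulate import (PlaceCellSpec, simulate_place_cell,
                                simulate_poisson_cell)
from tests.test_ratemaps import _fake_map


class TestStabilityIndex:
    def test_identical_trials_give_one(self, grid):
        rng = np.random.default_rng(0)
        row = rng.uniform(1, 5, 100)
        rm = _fake_map(grid, np.tile(row, (8, 1)))
        assert stability_index(rm) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, grid):
        rng = np.random.default_rng(1)
        rm = _fake_map(grid, rng.uniform(0, 5, (30, 100)))
        assert abs(stability_index(rm)) < 0.05

    def test_constant_pairs_skipped(self, grid):
        rows = np.vstack([np.full(100, 2.0),
                          np.linspace(0, 5, 100),
                          np.linspace(5, 0, 100)])
        rm = _fake_map(grid, rows)
        # only the non-constant pair counts: correlation -1
        assert stability_index(rm) == pytest.approx(-1.0)

    def test_decreases_with_center_jitter(self, traj30, grid):
        vals = {}
        for jit in (1.0, 8.0):
            spec = PlaceCellSpec(center_forth=100.0, center_back=None,
                                 width_sigma=8.0, peak_rate=10.0,
                                 baseline_rate=0.5, center_jitter_sd=jit,
                                 theta_mod_depth=0.0)
            st = simulate_place_cell(traj30, spec, seed=50)
            vals[jit] = stability_index(
                firing_rate_map(traj30, st, grid, "forth"))
        assert vals[1.0] > vals[8.0]


class TestSpatialInformation:
    def test_uniform_rate_gives_zero(self, grid):
        si = spatial_information(np.full(100, 3.0), np.ones(100), grid)
        assert si == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_of_hundred_gives_log2_100(self):
        g = BinGrid(reward_fraction=0.0, object_zones=())
        v = np.zeros(100)
        v[42] = 7.0
        assert spatial_information(v, np.ones(100), g) \
            == pytest.approx(np.log2(100))

    def test_half_track_firing_gives_one_bit(self):
        g = BinGrid(reward_fraction=0.0, object_zones=())
        v = np.zeros(100)
        v[:50] = 4.0
        assert spatial_information(v, np.ones(100), g) == pytest.approx(1.0)

    def test_invariant_to_rate_scaling(self, grid):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 8, 100)
        occ = rng.uniform(0.5, 1.5, 100)
        assert spatial_information(v, occ, grid) == pytest.approx(
            spatial_information(10.0 * v, occ, grid))

    def test_zero_occupancy_rejected(self, grid):
        with pytest.raises(ValueError):
            spatial_information(np.ones(100), np.zeros(100), grid)


class TestMutualInformation:
    def test_independent_rate_and_bin_gives_zero(self, grid):
        # rate varies by trial only: quartile label independent of bin
        rates = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 100))
        occ = np.ones((4, 100))
        assert mutual_information(rates, occ, grid) == pytest.approx(
            0.0, abs=1e-12)

    def test_planted_field_z_above_three(self, traj30, grid):
        spec = PlaceCellSpec(center_forth=100.0, center_back=None,
                             width_sigma=8.0, peak_rate=10.0,
                             baseline_rate=0.5, theta_mod_depth=0.0)
        st = simulate_place_cell(traj30, spec, seed=60)
        rm = firing_rate_map(traj30, st, grid, "forth")
        z = mutual_information_z(rm, traj30, st, n_surrogates=150, seed=61)
        assert z > 3.0

    def test_uniform_cell_z_near_zero(self, traj30, grid):
        st = simulate_poisson_cell(traj30, 4.0, seed=62)
        rm = firing_rate_map(traj30, st, grid, "forth")
        z = mutual_information_z(rm, traj30, st, n_surrogates=150, seed=63)
        assert abs(z) < 2.5


class TestLocalStability:
    def test_even_equals_odd_gives_one(self, grid):
        rng = np.random.default_rng(3)
        row = rng.uniform(1, 5, 100)
        rm = _fake_map(grid, np.tile(row, (8, 1)))
        ls = local_stability(rm)
        ab = grid.analyzed_bins
        assert np.allclose(ls[ab], 1.0)

    def test_noise_centered_on_zero(self, grid):
        rng = np.random.default_rng(4)
        rm = _fake_map(grid, rng.uniform(0, 5, (40, 100)))
        ls = local_stability(rm)
        assert abs(np.nanmean(ls[grid.analyzed_bins])) < 0.2

    def test_needs_four_trials(self, grid):
        rm = _fake_map(grid, np.ones((3, 100)))
        with pytest.raises(ValueError):
            local_stability(rm)


class TestUniformityTest:
    def test_even_distribution_high_p(self):
        fb = np.repeat(np.arange(32), 3)
        assert uniformity_test(fb, 32, seed=0) > 0.5

    def test_concentration_in_few_bins_rejected(self):
        fb = np.repeat(np.arange(8), 8)   # all fields in 8 of 32 bins
        assert uniformity_test(fb, 32, seed=1) <= 0.001

    def test_single_extreme_bin_trimmed_out(self):
        # the percentile trimming deliberately prevents one extreme bin
        # from driving the statistic
        fb = np.zeros(60, int)
        assert uniformity_test(fb, 32, seed=1) >= 0.5

    def test_needs_five_fields(self):
        with pytest.raises(ValueError):
            uniformity_test(np.array([1, 2, 3]), 32)


class TestMapSimilarity:
    def test_trial_equal_to_template_gives_one(self, grid):
        rng = np.random.default_rng(5)
        row = rng.uniform(0, 5, 100)
        maps = {"forth": np.tile(row, (4, 1)), "back": np.tile(row, (4, 1))}
        s = map_similarity(maps, maps, grid, template_is_self=False)
        assert np.allclose(s, 1.0)

    def test_leave_one_out_differs_from_naive(self, grid):
        rng = np.random.default_rng(6)
        tm = rng.uniform(0, 5, (5, 100))
        maps = {"forth": tm}
        naive = map_similarity(maps, {"forth": tm}, grid,
                               template_is_self=False)
        loo = map_similarity(maps, {"forth": tm}, grid,
                             template_is_self=True)
        assert not np.allclose(naive, loo)
        assert np.all(loo <= naive + 1e-12)
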