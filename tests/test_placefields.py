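"""Bootstrap place-field detection rules and per-field metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placecode import BinGrid, SessionManifest
from placecode.placefields import (LapField, PlaceField,
                                   _candidates_from_pvalues, _merge,
                                   bootstrap_pvalues,
                                   classify_object_responsive,
                                   classify_track_position,
                                   detect_lap_fields, detect_place_fields,
                                   field_dispersion, field_width,
                                   out_in_ratio)
from placecode.ratemaps import firing_rate_map
from placecode.simulate import simulate_poisson_cell


def p_vector(sig_runs, n=100):
    p = np.ones(n)
    for a, b in sig_runs:
        p[a:b + 1] = 0.001
    return p


class TestCandidateRules:
    def test_runs_shorter_than_four_bins_dropped(self, grid):
        cands = _candidates_from_pvalues(p_vector([(40, 42)]), grid)
        assert cands == []

    def test_gap_of_eight_bins_keeps_two_fields(self, grid):
        cands = _candidates_from_pvalues(p_vector([(30, 36), (44, 50)]), grid)
        assert len(cands) == 2

    def test_gap_of_five_bins_merges(self, grid):
        cands = _candidates_from_pvalues(p_vector([(30, 36), (41, 47)]), grid)
        assert len(cands) == 1
        assert cands[0][0] <= 30 and cands[0][1] >= 47

    def test_extension_requires_subthreshold_p(self, grid):
        p = p_vector([(40, 46)])
        p[36:40] = 0.2   # extendable
        p[47:] = 0.9     # not extendable
        (a, b), = _candidates_from_pvalues(p, grid)
        assert a == 36 and b == 46

    def test_extension_capped_at_five_bins(self, grid):
        p = np.full(100, 0.2)          # everywhere extendable
        p[40:47] = 0.001
        (a, b), = _candidates_from_pvalues(p, grid)
        assert a == 35 and b == 51

    def test_oversized_candidate_rejected(self, grid):
        cands = _candidates_from_pvalues(p_vector([(20, 80)]), grid)
        assert cands == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(10, 80), st.integers(0, 8)),
                    min_size=1, max_size=6))
    def test_merge_idempotent_and_order_independent(self, spans):
        ivs = [(a, min(89, a + w)) for a, w in spans]
        merged = _merge(ivs, 5)
        assert _merge(merged, 5) == merged
        assert _merge(list(reversed(ivs)), 5) == merged


class TestDetection:
    def test_planted_field_recovered(self, detected_fields):
        fields = detected_fields["forth"]
        assert len(fields) == 1
        f = fields[0]
        assert f.is_primary
        assert abs(f.peak_bin - 49.5) <= 2.5   # center 100 cm
        assert 4 <= f.size <= 45

    def test_uniform_cell_yields_no_field(self, traj30, grid):
        st_ = simulate_poisson_cell(traj30, 3.0, seed=20)
        rm = firing_rate_map(traj30, st_, grid, "forth")
        assert detect_place_fields(rm, n_boot=300, seed=21) == []

    def test_bootstrap_pvalues_valid_on_homogeneous_cells(self, traj30, grid):
        """Per-bin rejection rate at alpha 0.01 stays below 0.02."""
        rates = []
        for k in range(3):
            st_ = simulate_poisson_cell(traj30, 4.0, seed=30 + k)
            rm = firing_rate_map(traj30, st_, grid, "forth")
            p = bootstrap_pvalues(rm, n_boot=500, rng=40 + k)
            rates.append(np.mean(p[grid.analyzed_bins] < 0.01))
        assert np.mean(rates) <= 0.02

    def test_n_boot_floor(self, place_maps):
        with pytest.raises(ValueError):
            bootstrap_pvalues(place_maps["forth"], n_boot=50)

    def test_empty_train_returns_no_fields(self, traj30, grid):
        from placecode import SpikeTrain
        rm = firing_rate_map(traj30, SpikeTrain(0, np.array([])), grid,
                             "forth")
        assert detect_place_fields(rm, n_boot=300, seed=1) == []


class TestLapFields:
    def test_lap_fields_track_mean_field(self, place_maps, detected_fields):
        fields = [PlaceField(**{k: getattr(f, k) for k in
                                ("cell_id", "direction", "start", "stop",
                                 "peak_bin", "peak_rate")})
                  for f in detected_fields["forth"]]
        fields[0].is_primary = True
        detect_lap_fields(place_maps["forth"], fields, n_boot=300, seed=6)
        f = fields[0]
        rm = place_maps["forth"]
        n_laps_with_spikes = np.sum(rm.per_trial_counts.sum(axis=1) > 0)
        assert len(f.lap_fields) >= 0.8 * n_laps_with_spikes
        centers = np.array([lf.center_bin for lf in f.lap_fields])
        assert np.median(np.abs(centers - f.peak_bin)) <= 2
        assert f.dispersion is not None and f.dispersion < 10.0


class TestFieldMetrics:
    def test_triangular_field_width(self, grid):
        # symmetric triangle, 20-bin base, apex at bin 50, min 0
        v = np.zeros(100)
        for k in range(-10, 11):
            v[50 + k] = 10.0 * (1 - abs(k) / 10.0)
        f = PlaceField(0, "forth", 40, 60, 50, 10.0)
        complete, width = field_width(f, v, grid)
        assert complete
        assert width == pytest.approx(0.7 * 40.0, abs=0.2)

    def test_field_truncated_by_reward_zone_incomplete(self, grid):
        v = np.linspace(0, 10, 100)   # rises to the analysis edge
        f = PlaceField(0, "forth", 70, 89, 89, v[89])
        complete, width = field_width(f, v, grid)
        assert not complete and width is None

    def test_flat_field_undefined(self, grid):
        f = PlaceField(0, "forth", 40, 60, 50, 5.0)
        with pytest.warns(UserWarning):
            complete, width = field_width(f, np.full(100, 5.0), grid)
        assert not complete

    def test_dispersion_hand_case(self, grid):
        f = PlaceField(0, "forth", 40, 60, 50, 5.0)
        f.lap_fields = [LapField(k, 40, 60, 50 + (-1) ** k, 5.0)
                        for k in range(6)]
        assert field_dispersion(f, grid) == pytest.approx(2.0)

    def test_dispersion_zero_when_centers_match(self, grid):
        f = PlaceField(0, "forth", 40, 60, 50, 5.0)
        f.lap_fields = [LapField(k, 40, 60, 50, 5.0) for k in range(4)]
        assert field_dispersion(f, grid) == 0.0

    def test_dispersion_undefined_without_laps(self, grid):
        f = PlaceField(0, "forth", 40, 60, 50, 5.0)
        assert field_dispersion(f, grid) is None

    def test_out_in_ratio_uniform_is_one(self, grid):
        f = PlaceField(0, "forth", 40, 60, 50, 5.0)
        assert out_in_ratio(f, np.full(100, 5.0), [f], grid) \
            == pytest.approx(1.0)

    def test_out_in_ratio_silent_outside_is_zero(self, grid):
        v = np.zeros(100)
        v[40:61] = 5.0
        f = PlaceField(0, "forth", 40, 60, 50, 5.0)
        assert out_in_ratio(f, v, [f], grid) == 0.0

    def test_metrics_invariant_to_rate_rescaling(self, grid):
        v = np.zeros(100)
        v[40:61] = np.concatenate([np.linspace(0, 8, 11),
                                   np.linspace(8, 0, 11)[1:]])
        v += 1.0
        f = PlaceField(0, "forth", 40, 60, 50, 9.0)
        w1 = field_width(f, v, grid)[1]
        r1 = out_in_ratio(f, v, [f], grid)
        w3 = field_width(f, 3.0 * v, grid)[1]
        r3 = out_in_ratio(f, 3.0 * v, [f], grid)
        assert w1 == pytest.approx(w3)
        assert r1 == pytest.approx(r3)


class TestTrackClassAndOR:
    def test_track_position_classes(self, grid):
        ab = grid.analyzed_bins
        for pk, cls in [(ab[0], "EndTrack"), (50, "OnTrack"),
                        (ab[-1], "EndTrack")]:
            f = PlaceField(0, "forth", max(ab[0], pk - 3),
                           min(ab[-1], pk + 3), pk, 5.0)
            assert classify_track_position(f, grid) == cls

    def _field(self, d, peak):
        return PlaceField(0, d, peak - 3, peak + 3, peak, 5.0)

    def test_same_object_zone_both_directions(self, grid):
        m = SessionManifest()
        fbd = {"forth": [self._field("forth", 17)],    # 35 cm, crane
               "back": [self._field("back", 19)]}      # 38 cm, crane
        assert classify_object_responsive(fbd, m, grid)

    def test_different_objects_not_responsive(self, grid):
        m = SessionManifest()
        fbd = {"forth": [self._field("forth", 17)],    # crane
               "back": [self._field("back", 85)]}      # tree (170 cm)
        assert not classify_object_responsive(fbd, m, grid)

    def test_unidirectional_not_responsive(self, grid):
        m = SessionManifest()
        fbd = {"forth": [self._field("forth", 17)], "back": []}
        assert not classify_object_responsive(fbd, m, grid)

    def test_missing_zones_raise(self, grid):
        m = SessionManifest(individual_object_zones=())
        with pytest.raises(ValueError):
            classify_object_responsive({"forth": [], "back": []}, m, grid)
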