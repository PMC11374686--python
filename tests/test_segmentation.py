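import numpy as np
import pytest

from batmap.segmentation import (TraverseEpoch, conspecific_presence,
                                 detect_rest_locations, exclude_handling,
                                 flight_mask, rest_mask, segment_flights,
                                 smooth_bat_positions, smooth_human_coat)
from batmap.session import TrackedSeries, ValidationError


def _series(xyz, fs=100.0, subject="bat1"):
    xyz = np.asarray(xyz, float)
    t = np.arange(len(xyz)) / fs
    return TrackedSeries(subject, "tag", t, xyz)


class TestSmoothing:
    def test_quadratic_is_reproduced_exactly(self):
        t = np.arange(0, 5, 0.01)
        xyz = np.column_stack([t ** 2, 2 * t ** 2 + t, np.full_like(t, 1.0)])
        sm = smooth_bat_positions(_series(xyz))
        np.testing.assert_allclose(sm.xyz, xyz, atol=1e-9)

    def test_noise_rmse_halved(self, rng):
        t = np.arange(0, 20, 0.01)
        clean = np.column_stack([np.sin(0.3 * t), np.cos(0.3 * t),
                                 np.full_like(t, 1.0)])
        noisy = clean + rng.normal(0, 0.05, clean.shape)
        sm = smooth_bat_positions(_series(noisy))
        rmse_before = np.sqrt(((noisy - clean) ** 2).mean())
        rmse_after = np.sqrt(((sm.xyz - clean) ** 2).mean())
        assert rmse_after < 0.5 * rmse_before

    def test_constant_position_unchanged(self):
        xyz = np.tile([1.0, 2.0, 0.5], (500, 1))
        sm = smooth_bat_positions(_series(xyz))
        np.testing.assert_allclose(sm.xyz, xyz, atol=1e-12)

    def test_window_longer_than_series_rejected(self):
        xyz = np.zeros((30, 3))
        with pytest.raises(ValidationError):
            smooth_bat_positions(_series(xyz), window_s=1.0)

    def test_median_removes_single_outlier(self):
        xyz = np.tile([1.0, 1.0, 1.0], (600, 1))
        xyz[300] = [5.0, 5.0, 5.0]
        sm = smooth_human_coat(_series(xyz, subject="h1"))
        np.testing.assert_allclose(sm.xyz, 1.0, atol=1e-12)

    def test_median_keeps_monotone_ramp_interior(self):
        t = np.arange(0, 10, 0.01)
        xyz = np.column_stack([t, 2 * t, np.zeros_like(t)])
        sm = smooth_human_coat(_series(xyz, subject="h1"))
        interior = slice(150, -150)
        np.testing.assert_allclose(sm.xyz[interior], xyz[interior], atol=1e-9)

    def test_median_step_shift_bounded(self):
        xyz = np.tile([0.0, 0.0, 0.0], (1000, 1))
        xyz[500:] = [1.0, 0.0, 0.0]
        sm = smooth_human_coat(_series(xyz, subject="h1"))
        crossing = np.flatnonzero(sm.xyz[:, 0] > 0.5)[0]
        assert abs(crossing - 500) <= 100  # <= 1 s edge shift at 100 Hz


class TestFlights:
    def test_stationary_series_has_no_flights(self):
        xyz = np.tile([1.0, 1.0, 2.0], (2000, 1))
        assert segment_flights(_series(xyz)) == []

    def test_jitterfree_flights_recovered_exactly(self, jitterfree_bundle,
                                                  jitterfree_frames):
        _, bundle, _ = jitterfree_bundle
        true_fl = bundle.flights["bat1"]
        det = jitterfree_frames.flights["bat1"]
        assert len(det) == len(true_fl)
        for tf in true_fl:
            best = min(det, key=lambda f: abs(f.start_s - tf.start_s))
            assert abs(best.start_s - tf.start_s) <= 0.2
            assert abs(best.end_s - tf.end_s) <= 0.2

    def test_noisy_flights_recovered(self, fixture_bundle, fixture_frames):
        """With tracking noise, every flight is still found; endpoint error
        stays below half the smoothing window."""
        _, bundle, _ = fixture_bundle
        true_fl = bundle.flights["bat1"]
        det = fixture_frames.flights["bat1"]
        assert len(det) == len(true_fl)
        for tf in true_fl:
            best = min(det, key=lambda f: abs(f.start_s - tf.start_s))
            assert abs(best.start_s - tf.start_s) <= 0.5
            assert abs(best.end_s - tf.end_s) <= 0.5

    def test_flight_epochs_disjoint(self, fixture_frames):
        for bat, eps in fixture_frames.flights.items():
            ordered = sorted(eps, key=lambda f: f.start_s)
            for a, b in zip(ordered, ordered[1:]):
                assert a.end_s <= b.start_s

    def test_rest_and_flight_masks_disjoint(self, fixture_frames):
        bat = fixture_frames.session.recorded_bat
        sm = fixture_frames.smoothed[bat]
        fm = flight_mask(sm, fixture_frames.flights[bat])
        rm = fixture_frames.rest_masks[bat]
        assert not np.any(fm & rm)

    def test_velocity_of_constant_series_is_zero(self):
        xyz = np.tile([1.0, 1.0, 2.0], (500, 1))
        assert np.allclose(_series(xyz).speed(), 0.0)


class TestRest:
    def test_single_corner_centroid(self, rng):
        base = np.array([0.4, 0.4, 2.3])
        xyz = base + rng.normal(0, 0.02, (3000, 3))
        locs = detect_rest_locations(_series(xyz), k=1)
        np.testing.assert_allclose(locs[0].centroid_xyz, base, atol=0.05)

    def test_two_corners_found(self, rng):
        a = np.array([0.4, 0.4, 2.3]) + rng.normal(0, 0.02, (2000, 3))
        b = np.array([5.2, 0.4, 2.3]) + rng.normal(0, 0.02, (1000, 3))
        locs = detect_rest_locations(_series(np.vstack([a, b])), k=2)
        assert len(locs) == 2
        assert locs[0].n_members > locs[1].n_members
        np.testing.assert_allclose(locs[0].centroid_xyz, [0.4, 0.4, 2.3],
                                   atol=0.05)

    def test_all_moving_rejected(self):
        t = np.arange(0, 5, 0.01)
        xyz = np.column_stack([5 * t, np.zeros_like(t), np.zeros_like(t)])
        with pytest.raises(ValidationError):
            detect_rest_locations(_series(xyz))

    @pytest.mark.parametrize("offset,speed,expected", [
        ((0, 0, 0), 0.0, True),
        ((2.5, 0, 0), 0.0, False),      # beyond the 2-m distance rule
        ((0, 0, 0), 0.6, False),        # above the 0.4 m/s velocity rule
    ])
    def test_rest_mask_rules(self, offset, speed, expected):
        centroid = np.array([1.0, 1.0, 2.0])
        n = 200
        t = np.arange(n) / 100.0
        xyz = np.tile(centroid + np.asarray(offset, float), (n, 1))
        xyz[:, 0] += speed * t
        m = rest_mask(TrackedSeries("b", "tag", t, xyz), centroid)
        assert bool(m[n // 2]) is expected


class TestTraverses:
    def test_jitterfree_traverses_recovered(self, jitterfree_bundle,
                                            jitterfree_frames):
        _, bundle, _ = jitterfree_bundle
        det = jitterfree_frames.traverses
        assert len(det) == len(bundle.traverses)
        for tt in bundle.traverses:
            best = min(det, key=lambda e: abs(e.start_s - tt.start_s))
            assert best.human_id == tt.human
            assert abs(best.start_s - tt.start_s) <= 0.2
            assert abs(best.end_s - tt.end_s) <= 0.2

    def test_noisy_traverses_all_found(self, fixture_bundle, fixture_frames):
        _, bundle, _ = fixture_bundle
        det = fixture_frames.traverses
        assert len(det) == len(bundle.traverses)

    def test_exclusion_buffer_is_one_second(self):
        ep = TraverseEpoch(0.0, 20.0, "h1")
        exclude_handling(ep, [(5.0, 7.0)], buffer_s=1.0)
        assert ep.excluded_spans == [[4.0, 8.0]]

    def test_abutting_events_merge(self):
        ep = TraverseEpoch(0.0, 20.0, "h1")
        exclude_handling(ep, [(5.0, 6.0), (7.5, 8.5)], buffer_s=1.0)
        assert ep.excluded_spans == [[4.0, 9.5]]

    def test_no_events_no_spans(self):
        ep = TraverseEpoch(0.0, 20.0, "h1")
        exclude_handling(ep, [])
        assert ep.excluded_spans == []

    def test_event_outside_epoch_rejected(self):
        ep = TraverseEpoch(0.0, 20.0, "h1")
        with pytest.raises(ValidationError):
            exclude_handling(ep, [(25.0, 26.0)])


class TestConspecificPresence:
    def _other(self, xyz):
        return _series(xyz, subject="bat2")

    def test_present_at_tripod(self):
        tripod = np.array([1.0, 1.0, 1.3])
        other = self._other(np.tile(tripod + [0.1, 0, 0], (500, 1)))
        assert conspecific_presence(other, tripod, 2.5) is True

    def test_absent_when_far(self):
        tripod = np.array([1.0, 1.0, 1.3])
        other = self._other(np.tile([4.0, 4.0, 1.3], (500, 1)))
        assert conspecific_presence(other, tripod, 2.5) is False

    def test_flying_past_not_present(self):
        tripod = np.array([1.0, 1.0, 1.3])
        t = np.arange(500) / 100.0
        xyz = np.column_stack([1.0 + 2.0 * (t - 2.5), np.full_like(t, 1.0),
                               np.full_like(t, 1.3)])
        assert conspecific_presence(_series(xyz, subject="bat2"),
                                    tripod, 2.5) is False

    def test_tracking_gap_gives_unknown(self):
        tripod = np.array([1.0, 1.0, 1.3])
        other = self._other(np.tile(tripod, (100, 1)))
        assert conspecific_presence(other, tripod, 50.0) is None
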