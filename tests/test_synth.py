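import json

import numpy as np
import pytest

from batmap.session import load_session
from batmap.synth import (SynthParams, UnitTuning, fixture_params,
                          fixture_units, generate_behavior, generate_spikes,
                          generate_session, make_fixture_suite, rate_on_grid)


def _small_params(**kw):
    defaults = dict(n_blocks=2, rest_duration_range=(10.0, 18.0),
                    n_traverses_per_human=3, with_conspecific=False)
    defaults.update(kw)
    return SynthParams(**defaults)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        b1 = generate_behavior(_small_params(), seed=4)
        b2 = generate_behavior(_small_params(), seed=4)
        np.testing.assert_array_equal(b1.session.bats["bat1"].xyz,
                                      b2.session.bats["bat1"].xyz)
        np.testing.assert_array_equal(
            b1.session.humans["h1"]["coat"].xyz,
            b2.session.humans["h1"]["coat"].xyz)

    def test_spikes_reproducible_and_unit_independent(self):
        bundle = generate_behavior(_small_params(), seed=4)
        t1 = generate_spikes(bundle, UnitTuning("a", 2.0), seed=4, unit_index=0)
        t2 = generate_spikes(bundle, UnitTuning("a", 2.0), seed=4, unit_index=0)
        np.testing.assert_array_equal(t1.spike_times, t2.spike_times)
        # adding a later unit never changes an earlier unit's draws
        t3 = generate_spikes(bundle, UnitTuning("b", 1.0), seed=4, unit_index=1)
        np.testing.assert_array_equal(
            t1.spike_times,
            generate_spikes(bundle, UnitTuning("a", 2.0), 4, 0).spike_times)


class TestBehavior:
    def test_zero_jitter_flights_identical(self):
        params = _small_params()
        params.path_jitter_m = 0.0
        params.rest_noise_m = 0.0
        bundle = generate_behavior(params, seed=2)
        ses = bundle.session
        from batmap.trajectories import resample_equal_time
        by_target = {}
        for f in bundle.flights["bat1"]:
            if f.target != "rest":
                sel = (ses.bats["bat1"].t >= f.start_s) & \
                      (ses.bats["bat1"].t < f.end_s)
                t = ses.bats["bat1"].t[sel]
                by_target.setdefault(f.target, []).append(
                    resample_equal_time(t, ses.bats["bat1"].xyz[sel]).ravel())
        for target, paths in by_target.items():
            for p in paths[1:]:
                r = np.corrcoef(paths[0], p)[0, 1]
                assert r > 0.9999

    def test_jitter_separates_within_from_across(self):
        params = _small_params()
        params.path_jitter_m = 0.05
        bundle = generate_behavior(params, seed=2)
        ses = bundle.session
        from batmap.trajectories import downsample_flight
        shapes, targets = [], []
        for f in bundle.flights["bat1"]:
            if f.target == "rest":
                continue
            sel = (ses.bats["bat1"].t >= f.start_s) & \
                  (ses.bats["bat1"].t < f.end_s)
            shapes.append(downsample_flight(ses.bats["bat1"].xyz[sel]).ravel())
            targets.append(f.target)
        shapes = np.asarray(shapes)
        within, across = [], []
        for i in range(len(shapes)):
            for j in range(i + 1, len(shapes)):
                d = np.linalg.norm(shapes[i] - shapes[j])
                (within if targets[i] == targets[j] else across).append(d)
        assert np.mean(within) < np.mean(across)

    def test_no_traverses_means_slow_coat_outside_swaps(self):
        params = _small_params(n_traverses_per_human=0)
        bundle = generate_behavior(params, seed=3)
        coat = bundle.session.humans["h1"]["coat"]
        speed = coat.speed()
        # outside the block-boundary swap walks, the coat tag never reaches
        # the traverse threshold
        swap_like = np.zeros(coat.n, bool)
        for k in range(params.n_blocks + 1):
            t0 = k * params.block_s
            sel = (coat.t >= t0 - 1.0) & (coat.t <= t0 + 12.0)
            swap_like |= sel
        assert speed[~swap_like].max() < 0.4

    def test_schedule_counterbalanced(self):
        # 12 blocks = two visits per tripod pair -> exact balance
        params = SynthParams(n_blocks=12, n_traverses_per_human=0)
        bundle = generate_behavior(params, seed=1)
        time_at = {}
        for b in bundle.session.schedule:
            for h, loc in b.assignment.items():
                time_at[(h, loc)] = time_at.get((h, loc), 0) + b.end_s - b.start_s
        per_pair = set(time_at.values())
        assert len(per_pair) == 1  # equal time per human per tripod

    def test_behavior_passes_session_invariants(self):
        bundle = generate_behavior(_small_params(), seed=6)
        for s in bundle.session._all_series():
            assert np.all(np.diff(s.t) > 0)
            assert not np.isnan(s.xyz).any()


class TestSpikes:
    def test_zero_rate_gives_no_spikes(self):
        bundle = generate_behavior(_small_params(), seed=5)
        train = generate_spikes(bundle, UnitTuning("z", 0.0), seed=5)
        assert train.n_spikes == 0

    def test_constant_rate_count_unbiased(self):
        bundle = generate_behavior(_small_params(n_traverses_per_human=0),
                                   seed=5)
        T = bundle.t[-1] - bundle.t[0]
        counts = [generate_spikes(bundle, UnitTuning("c", 3.0), seed=s).n_spikes
                  for s in range(200)]
        expected = 3.0 * T
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_counts_scale_linearly_with_peak_rate(self):
        bundle = generate_behavior(_small_params(), seed=5)
        rates = [1.0, 2.0, 4.0]
        counts = []
        for r in rates:
            c = [generate_spikes(bundle, UnitTuning("c", r), seed=s).n_spikes
                 for s in range(30)]
            counts.append(np.mean(c))
        slope = np.polyfit(rates, counts, 1)[0]
        T = bundle.t[-1] - bundle.t[0]
        assert abs(slope - T) / T < 0.05

    def test_negative_rate_rejected(self):
        bundle = generate_behavior(_small_params(), seed=5)
        with pytest.raises(ValueError):
            rate_on_grid(bundle, UnitTuning("bad", -1.0))

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            UnitTuning("bad", 1.0, identity_gain={("T1", "h1"): 0.0}).validate()


class TestFixtureSuite:
    def test_suite_written_and_loadable(self, tmp_path):
        truth = make_fixture_suite(0, tmp_path)
        assert set(truth) == {"null", "place", "identity", "human_pos"}
        loaded = load_session(tmp_path / "session")
        assert {u.unit_id for u in loaded.units} == set(truth)
        gt = json.loads((tmp_path / "ground_truth.json").read_text())
        assert gt["identity"]["is_identity_modulated"]
        assert gt["place"]["is_spatial_self"]
        assert gt["human_pos"]["tuned_humans"] == ["h1"]
        assert not gt["null"]["is_spatial_self"]

    def test_ground_truth_consistent_with_tuning(self):
        for t in fixture_units():
            from batmap.synth import GroundTruth
            g = GroundTruth.from_tuning(t)
            assert g.is_identity_modulated == bool(
                [v for v in t.identity_gain.values() if v != 1])
            assert g.is_human_position_tuned == bool(t.human_fields)
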