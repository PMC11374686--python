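from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from batmap.config import AnalysisConfig
from batmap.identity import (baseline_rate, derive_seed, event_trials,
                             identity_permutation_tests,
                             identity_tests_excluding_conspecific,
                             label_permutation_test, reward_metrics,
                             two_group_permutation, window_count, window_rate)
from batmap.session import SpikeTrain


def _train(times, span=(0.0, 100.0)):
    return SpikeTrain("u", np.asarray(times, float), span)


class TestWindowRate:
    def test_four_spikes_is_two_hz(self):
        train = _train([10.0, 10.5, 11.0, 11.4])
        assert window_rate(train, 10.0, "landing") == pytest.approx(2.0)

    def test_empty_window_zero(self):
        assert window_rate(_train([50.0]), 10.0, "landing") == 0.0

    def test_half_open_boundaries(self):
        # landing window is [t - 0.25, t + 1.75)
        train = _train([9.75, 11.75])
        assert window_count(train, 10.0, "landing") == 1
        train2 = _train([11.749999])
        assert window_count(train2, 10.0, "landing") == 1

    def test_takeoff_window_position(self):
        # take-off window is [t - 1.75, t + 0.25)
        train = _train([8.3, 10.2, 10.3])
        assert window_count(train, 10.0, "take_off") == 2


class TestPermutationCore:
    def test_exact_enumeration_matches_brute_force(self, rng):
        """Monte-Carlo p agrees with a full-enumeration oracle within 0.01."""
        values = rng.normal(0, 1, 9)
        labels = np.array([True] * 4 + [False] * 5)
        emp, _, null, n_distinct = two_group_permutation(
            values, labels, n_perm_max=10_000, seed=0)
        # independent brute-force oracle over all C(9, 4) assignments
        oracle = []
        for idx in combinations(range(9), 4):
            g1 = np.zeros(9, bool)
            g1[list(idx)] = True
            oracle.append(abs(values[g1].mean() - values[~g1].mean()))
        oracle = np.asarray(oracle)
        assert n_distinct == comb(9, 4) == oracle.size
        p_impl = (1 + (null >= emp).sum()) / (1 + null.size)
        p_oracle = (1 + (oracle >= emp).sum()) / (1 + oracle.size)
        assert abs(p_impl - p_oracle) <= 0.01

    def test_monte_carlo_matches_enumeration_for_large_groups(self, rng):
        values = rng.normal(0, 1, 24)
        labels = np.zeros(24, bool)
        labels[:12] = True
        emp, _, null_mc, _ = two_group_permutation(
            values, labels, n_perm_max=10_000, seed=1,
            enumerate_limit=1)          # force random relabeling
        emp2, _, null_en, _ = two_group_permutation(
            values, labels, n_perm_max=10_000, seed=1)
        assert emp == pytest.approx(emp2)
        p_mc = (1 + (null_mc >= emp).sum()) / (1 + null_mc.size)
        p_en = (1 + (null_en >= emp).sum()) / (1 + null_en.size)
        assert abs(p_mc - p_en) <= 0.03

    def test_label_symmetry(self, rng):
        values = rng.normal(0, 1, 12)
        labels = np.array([True] * 6 + [False] * 6)
        e1, s1, n1, _ = two_group_permutation(values, labels, seed=5)
        e2, s2, n2, _ = two_group_permutation(values, ~labels, seed=5)
        assert e1 == pytest.approx(e2)
        assert s1 == -s2
        np.testing.assert_allclose(np.sort(n1), np.sort(n2))

    def test_empirical_diff_nonnegative(self, rng):
        values = rng.normal(0, 1, 10)
        labels = np.array([True] * 5 + [False] * 5)
        emp, _, _, _ = two_group_permutation(values, labels)
        assert emp >= 0


class TestInclusionRules:
    def _test(self, rates, labels, counts, **kw):
        return label_permutation_test(rates, labels, counts, "u", "T1",
                                      "landing", AnalysisConfig(), **kw)

    def test_four_vs_four_is_includable(self, rng):
        rates = rng.normal(5, 1, 8)
        labels = ["h1"] * 4 + ["h2"] * 4
        counts = np.full(8, 4)
        res = self._test(rates, labels, counts)
        assert res.analyzable            # C(8,4)=70, 1/70 < 0.02
        assert res.n_perm == 70

    def test_three_vs_three_resolution_too_coarse(self, rng):
        # C(6,3) = 20 distinct assignments -> resolution 0.05 > 0.02, even
        # when the per-label trial floor is relaxed to admit the groups
        rates = rng.normal(5, 1, 6)
        cfg = AnalysisConfig(min_trials_per_label=3)
        res = label_permutation_test(rates, ["h1"] * 3 + ["h2"] * 3,
                                     np.full(6, 4), "u", "T1", "landing", cfg)
        assert not res.analyzable
        assert "resolution" in res.note

    def test_spike_minimum_enforced(self):
        rates = np.ones(10)
        counts = np.array([2, 2, 2, 2, 2, 1, 1, 1, 0, 0])  # 13 < 15 spikes
        res = self._test(rates, ["h1"] * 5 + ["h2"] * 5, counts)
        assert not res.analyzable

    def test_single_label_not_analyzable(self):
        res = self._test(np.ones(8), ["h1"] * 8, np.full(8, 4))
        assert not res.analyzable


class TestTypeIControl:
    def test_null_units_super_uniform(self, rng):
        """Exchangeable labels: flagged fraction stays near alpha."""
        n_units, flagged = 400, 0
        for i in range(n_units):
            rates = rng.poisson(8, 12) / 2.0
            labels = np.array(["h1"] * 6 + ["h2"] * 6)
            counts = np.maximum((rates * 2).astype(int), 2)
            res = label_permutation_test(rates, labels, counts, f"u{i}", "T1",
                                         "landing", AnalysisConfig(),
                                         seed=derive_seed(0, i))
            if res.analyzable:
                level = 1.0 - 0.05
                flagged += res.empirical_diff > np.quantile(res.null_diffs,
                                                            level)
        se = np.sqrt(0.05 * 0.95 / n_units)
        assert flagged / n_units <= 0.05 + 3 * se


@pytest.fixture(scope="module")
def identity_results(fixture_frames, fixture_units, fixture_bundle):
    session, _, _ = fixture_bundle
    cfg = session.config
    out = {}
    for uid in ("null", "identity"):
        trials = event_trials(fixture_frames.flights["bat1"],
                              fixture_units[uid].spike_train,
                              {"take_off": cfg.takeoff_window,
                               "landing": cfg.landing_window})
        out[uid] = identity_permutation_tests(trials, uid, cfg, seed=0)
    return out


class TestFixtureRecovery:
    def test_identity_unit_detected_at_its_tripod_only(self, identity_results,
                                                       fixture_bundle):
        _, _, truth = fixture_bundle
        res = identity_results["identity"]
        sig_locs = {r.location_id for r in res if r.significant}
        assert sig_locs == set(truth["identity"].identity_locations)

    def test_null_unit_not_modulated(self, identity_results):
        assert not any(r.significant for r in identity_results["null"])

    def test_exclusion_variant_preserves_true_modulation(
            self, fixture_frames, fixture_units, fixture_bundle):
        session, _, truth = fixture_bundle
        cfg = session.config
        trials = event_trials(fixture_frames.flights["bat1"],
                              fixture_units["identity"].spike_train,
                              {"take_off": cfg.takeoff_window,
                               "landing": cfg.landing_window})
        res = identity_tests_excluding_conspecific(trials, "identity", cfg, 0)
        sig_locs = {r.location_id for r in res if r.significant}
        assert set(truth["identity"].identity_locations) <= sig_locs


class TestRewardMetrics:
    def test_flat_unit_changes_near_one(self, rng):
        span = (0.0, 400.0)
        spikes = np.sort(rng.uniform(0, 400, 2400))  # 6 Hz homogeneous
        train = SpikeTrain("u", spikes, span)
        times = np.arange(20.0, 380.0, 20.0)
        trials = pd.DataFrame({
            "flight_id": np.arange(times.size), "event": "landing",
            "location": "T1", "event_time": times,
            "human": ["h1", "h2"] * (times.size // 2),
            "conspecific_present": False,
            "rate": [window_rate(train, t, "landing") for t in times],
            "count": [window_count(train, t, "landing") for t in times],
        })
        out = reward_metrics(train, trials, AnalysisConfig())
        loc = out["per_location"]["T1"]
        for h in loc:
            assert loc[h]["mean_rate_change"] == pytest.approx(1.0, abs=0.35)

    def test_identical_rate_vectors_spearman_one(self, rng):
        span = (0.0, 400.0)
        # regular background spikes plus a deterministic burst after every
        # landing: both humans' average peri-landing rate vectors coincide
        base = np.arange(0.05, 400.0, 0.5)
        times = np.arange(20.0, 380.0, 20.0)
        burst = np.concatenate([t + np.linspace(0.1, 0.9, 9) for t in times])
        train = SpikeTrain("u", np.sort(np.concatenate([base, burst])), span)
        trials = pd.DataFrame({
            "flight_id": np.arange(times.size), "event": "landing",
            "location": "T1", "event_time": times,
            "human": ["h1", "h2"] * (times.size // 2),
            "conspecific_present": False,
            "rate": [window_rate(train, t, "landing") for t in times],
            "count": [window_count(train, t, "landing") for t in times],
        })
        out = reward_metrics(train, trials, AnalysisConfig())
        assert out["spearman_r"] > 0.9

    def test_zero_baseline_not_analyzable(self):
        train = SpikeTrain("u", np.array([10.1, 10.2, 10.3] * 6).flatten(),
                           (0.0, 20.0))
        trials = pd.DataFrame({
            "flight_id": [0], "event": ["landing"], "location": ["T1"],
            "event_time": [10.0], "human": ["h1"],
            "conspecific_present": [False], "rate": [9.0], "count": [18]})
        out = reward_metrics(train, trials, AnalysisConfig())
        assert not out["analyzable"]


def test_seed_derivation_stable_and_bounded():
    s1 = derive_seed(3, "u1", "T1", "landing")
    s2 = derive_seed(3, "u1", "T1", "landing")
    s3 = derive_seed(3, "u1", "T2", "landing")
    assert s1 == s2 != s3
    assert 0 <= s1 < 2 ** 31
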