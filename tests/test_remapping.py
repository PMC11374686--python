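import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batmap.ratemaps import BinnedTrajectory1D, RateMap1D, linearize_flights
from batmap.remapping import (context_pair_metrics, map_metrics_1d,
                              null_nonpaired, null_trial_shuffle,
                              remapping_score, stability_even_odd,
                              temporal_stability_halves, trajectory_remapping)
from batmap.session import ValidationError


class TestScore:
    @pytest.mark.parametrize("r1,r2,expected", [
        (5.0, 5.0, 0.0),
        (5.0, 0.0, 1.0),
        (3.0, 1.0, 0.5),
    ])
    def test_closed_forms(self, r1, r2, expected):
        assert remapping_score(r1, r2) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            remapping_score(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            remapping_score(-1.0, 2.0)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.floats(0.0, 50.0), st.floats(1e-6, 50.0), st.floats(0.01, 100.0))
    def test_symmetry_scale_invariance_and_range(self, r1, r2, k):
        s = remapping_score(r1, r2)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(remapping_score(r2, r1))
        assert s == pytest.approx(remapping_score(k * r1, k * r2), abs=1e-9)

    def test_bulk_random_pairs(self, rng):
        a = rng.gamma(2.0, 2.0, 10_000)
        b = rng.gamma(2.0, 2.0, 10_000)
        s = np.abs(a - b) / (a + b)
        s_swap = np.abs(b - a) / (b + a)
        assert ((s >= 0) & (s <= 1)).all()
        np.testing.assert_allclose(s, s_swap)


def _map1d(rates, occ=None):
    rates = np.asarray(rates, float)
    occ = np.ones_like(rates) if occ is None else np.asarray(occ, float)
    p = occ / occ.sum()
    return RateMap1D(0.15, rates.size * 0.15, occ, np.zeros_like(rates),
                     rates, np.ones(rates.size, bool), p,
                     float((p * rates).sum()))


class TestMapMetrics:
    def test_identical_maps(self):
        m = _map1d([1, 2, 5, 2, 1])
        r, d = map_metrics_1d(m, m)
        assert r == pytest.approx(1.0)
        assert d == 0.0

    def test_ten_bin_shift_gives_1_5_m(self):
        base = np.zeros(30)
        base[5] = 4.0
        shifted = np.roll(base, 10)
        r, d = map_metrics_1d(_map1d(base + 0.1), _map1d(shifted + 0.1))
        assert d == pytest.approx(1.5)

    def test_scaled_map_correlates_perfectly(self):
        m1 = _map1d([1, 2, 5, 2, 1])
        m2 = _map1d(2 * np.array([1, 2, 5, 2, 1.0]))
        r, _ = map_metrics_1d(m1, m2)
        assert r == pytest.approx(1.0)
        assert remapping_score(m1.mean_rate, m2.mean_rate) == \
            pytest.approx(1 / 3)

    def test_peak_tie_broken_to_smallest_index(self):
        m = _map1d([1, 5, 5, 1])
        assert m.peak_bin() == 1


class TestNulls:
    def test_nonpaired_excludes_self(self, rng):
        maps1 = {f"u{i}": _map1d(rng.gamma(2, 2, 20) + 0.1) for i in range(6)}
        maps2 = {f"u{i}": _map1d(rng.gamma(2, 2, 20) + 0.1) for i in range(6)}
        # correlate each unit's own h1 map against its own h2 map and against
        # the null pairing: identical maps across dicts would betray self-pairs
        same = {u: maps1[u] for u in maps1}
        corrs, dists = null_nonpaired(maps1, same, seed=0)
        for u, m in maps1.items():
            pass  # draw validity checked via distribution below
        assert len(corrs) == 6
        # independent random fields: null correlation centred near zero
        assert abs(np.nanmean(corrs)) < 0.5

    def test_single_unit_rejected(self):
        with pytest.raises(ValidationError):
            null_nonpaired({"u": _map1d([1, 2])}, {"u": _map1d([1, 2])})

    def test_trial_shuffle_preserves_group_sizes_and_rates(self, rng):
        flights = []
        t0 = 0.0
        for _ in range(12):
            t = t0 + np.arange(0, 2.0, 0.01)
            x = 3.0 * (t - t0)
            flights.append((t, np.column_stack([x, 0 * x, 0 * x + 1])))
            t0 = t[-1] + 5.0
        lin, L = linearize_flights(flights)
        binned = BinnedTrajectory1D(lin, L)
        by_human = {"h1": lin[:6], "h2": lin[6:]}
        spikes = np.sort(rng.uniform(0, t0, 200))
        null = null_trial_shuffle(binned, by_human, spikes, 300, seed=1)
        assert null.shape == (300,)
        assert np.nanmax(null) <= 1.0 and np.nanmin(null) >= 0.0

    def test_identity_gain_unit_beats_score_null(self, fixture_frames,
                                                 fixture_units,
                                                 fixture_bundle):
        """The gain unit shows rate remapping: score above the shuffle null
        with preserved field location (high correlation)."""
        from batmap.pipeline import run_all
        # reuse the pipeline's remapping table on the fixture session
        session, _, truth = fixture_bundle
        res = run_all(session, seed=0, frames_list=("self_1d",))
        remap = res["remapping"]
        ident = remap[remap["unit"] == "identity"]
        assert (ident["score_p"] < 0.05).any()
        best = ident.loc[ident["score_p"].idxmin()]
        assert best["correlation"] > 0.5
        assert best["peak_distance_m"] <= 0.6


class TestContexts:
    def _map2d(self, rng, shape=(10, 10), n_spikes=50, field=None):
        from batmap.ratemaps import RateMap2D
        occ = np.full(shape, 0.5)
        rate = rng.gamma(2.0, 1.0, shape)
        if field is not None:
            rate[field] += 8.0
        valid = np.ones(shape, bool)
        spk = np.zeros(shape)
        spk.flat[rng.choice(spk.size, n_spikes)] = 1.0
        p = (occ / occ.sum())[valid]
        return RateMap2D(0.15, (0, 0), occ, spk, rate, valid, p,
                         float((p * rate[valid]).sum()))

    def test_low_shared_fraction_excluded(self, rng):
        a = self._map2d(rng)
        b = self._map2d(rng)
        b.valid[:, :8] = False
        a.valid[:, 2:] = False
        assert context_pair_metrics(a, b) is None

    def test_too_few_spikes_excluded(self, rng):
        a = self._map2d(rng, n_spikes=50)
        b = self._map2d(rng, n_spikes=15)
        assert context_pair_metrics(a, b) is None

    def test_matching_contexts_pass(self, rng):
        a = self._map2d(rng, field=(slice(2, 4), slice(2, 4)))
        b = self._map2d(rng, field=(slice(2, 4), slice(2, 4)))
        pair = context_pair_metrics(a, b)
        assert pair is not None
        assert pair.metrics.map_correlation > 0.5
        assert pair.metrics.peak_or_centroid_distance < 0.5


class TestStability:
    def _flights(self, n, rng=None, rate_fn=None):
        flights, spikes = [], []
        t0 = 0.0
        for i in range(n):
            t = t0 + np.arange(0, 2.0, 0.01)
            x = 3.0 * (t - t0)
            flights.append((t, np.column_stack([x, 0 * x, 0 * x + 1])))
            if rate_fn is not None:
                r = rate_fn(i, x)
                draws = rng.random(t.size) < r * 0.01
                spikes.append(t[draws])
            t0 = t[-1] + 5.0
        lin, L = linearize_flights(flights)
        spk = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        return lin, L, spk

    def test_stable_field_high_even_odd_correlation(self, rng):
        rate_fn = lambda i, x: 15.0 * np.exp(-0.5 * ((x - 3) / 0.7) ** 2) + 1.0
        lin, L, spk = self._flights(60, rng, rate_fn)
        r = stability_even_odd(lin, L, spk)
        assert r > 0.8

    def test_too_few_flights_rejected(self):
        lin, L, _ = self._flights(3)
        with pytest.raises(ValidationError):
            stability_even_odd(lin, L, np.array([0.5]))

    def test_stationary_modulation_within_null(self, rng):
        rate_fn = lambda i, x: np.full_like(x, 5.0)
        lin, L, spk = self._flights(30, rng, rate_fn)
        emp, null = temporal_stability_halves(lin, spk, 500, seed=2)
        assert emp <= np.quantile(null, 0.99)

    def test_drifting_gain_detected(self, rng):
        rate_fn = lambda i, x: np.full_like(x, 1.0 + 0.4 * i)  # ramps up
        lin, L, spk = self._flights(30, rng, rate_fn)
        emp, null = temporal_stability_halves(lin, spk, 500, seed=2)
        assert emp > np.quantile(null, 0.95)
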