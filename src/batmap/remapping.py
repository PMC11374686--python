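"""Rate- vs global-remapping metrics and their null constructions.

For a unit on one trajectory, the 1D rate maps built from flights to the
two human landing targets are compared by (a) their Pearson correlation
over common valid bins, (b) the distance between their peak bins, and
(c) the remapping score |r1 - r2| / (r1 + r2) on the two maps' mean rates
(0 = no rate change, 1 = one rate dominates).  The correlation/peak-distance
nulls pair maps of *different* units (global remapping: fields move at
random); the score null shuffles the human labels across flights of the
same unit (no rate remapping).  The 2D analogue compares maps restricted to
the two highest-occupancy human-configuration 'contexts', with centroid
distance in place of peak distance.

Stability checks: even/odd-flight split-half Spearman correlation of 1D
maps, and a first-half vs second-half mean-rate correlation against a
random-split null (tests whether identity modulation was present from the
first trial or drifted in).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ratemaps import BinnedTrajectory1D, RateMap1D, RateMap2D
from .session import ValidationError


def remapping_score(rate1: float, rate2: float) -> float:
    """|r1 - r2| / (r1 + r2); symmetric, scale-invariant, in [0, 1]."""
    if rate1 < 0 or rate2 < 0:
        raise ValueError("mean rates must be non-negative")
    total = rate1 + rate2
    if total == 0:
        raise ValidationError("remapping score undefined for two zero rates")
    return abs(rate1 - rate2) / total


def _common_valid(map_a, map_b):
    return map_a.valid & map_b.valid


def map_metrics_1d(map_h1: RateMap1D, map_h2: RateMap1D):
    """(Pearson r over common valid bins, peak distance in m)."""
    common = _common_valid(map_h1, map_h2)
    if common.sum() < 3:
        r = np.nan
    else:
        a, b = map_h1.rate[common], map_h2.rate[common]
        r = np.nan if (np.std(a) == 0 or np.std(b) == 0) else \
            float(stats.pearsonr(a, b).statistic)
    dist = abs(map_h1.peak_bin() - map_h2.peak_bin()) * map_h1.bin_size
    return r, float(dist)


def map_metrics_2d(map_a: RateMap2D, map_b: RateMap2D):
    """(Pearson r over common valid bins, center-of-mass distance in m)."""
    common = _common_valid(map_a, map_b)
    if common.sum() < 3:
        r = np.nan
    else:
        a, b = map_a.rate[common], map_b.rate[common]
        r = np.nan if (np.std(a) == 0 or np.std(b) == 0) else \
            float(stats.pearsonr(a, b).statistic)
    dist = float(np.linalg.norm(map_a.center_of_mass() - map_b.center_of_mass()))
    return r, dist


@dataclass
class RemapMetrics:
    map_correlation: float
    peak_or_centroid_distance: float
    score: float
    null_correlation: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_distance: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_score: np.ndarray = field(default_factory=lambda: np.empty(0))


def null_nonpaired(maps_h1_by_unit: dict, maps_h2_by_unit: dict, seed=0,
                   metric_fn=map_metrics_1d):
    """Global-remapping null: metrics between maps of non-paired units.

    One random non-self pairing draw per unit.  Returns (null correlations,
    null distances).  Degenerate with a single unit (logged by the caller).
    """
    units = sorted(set(maps_h1_by_unit) & set(maps_h2_by_unit))
    if len(units) < 2:
        raise ValidationError("non-paired null needs at least two units")
    rng = np.random.default_rng(seed)
    corrs, dists = [], []
    for u in units:
        others = [v for v in units if v != u]
        v = others[rng.integers(len(others))]
        r, d = metric_fn(maps_h1_by_unit[u], maps_h2_by_unit[v])
        corrs.append(r)
        dists.append(d)
    return np.asarray(corrs), np.asarray(dists)


def null_trial_shuffle(binned: BinnedTrajectory1D, flights_by_human: dict,
                       spike_times, n_shuffles: int = 1000, seed=0):
    """No-rate-remapping null: shuffle human labels across flights, rebuild
    the per-human 1D maps and collect remapping scores.

    ``flights_by_human`` maps human id -> list of LinearizedFlight.  Only
    the labels move: each shuffle redraws which flights count as human 1,
    preserving the two group sizes and every flight's own spikes.
    """
    humans = sorted(flights_by_human)
    if len(humans) != 2:
        raise ValidationError("trial-shuffle null needs exactly two humans")
    all_flights = flights_by_human[humans[0]] + flights_by_human[humans[1]]
    n1 = len(flights_by_human[humans[0]])
    # per-flight mean rates (spikes / flight duration) are sufficient for the
    # score, which depends only on the groups' mean rates over occupancy
    spike_times = np.asarray(spike_times, float)
    counts = np.array([np.sum((spike_times >= f.t[0])
                              & (spike_times <= f.t[-1])) for f in all_flights])
    durs = np.array([f.t[-1] - f.t[0] for f in all_flights])
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    idx_all = np.arange(len(all_flights))
    for s in range(n_shuffles):
        pick = rng.permutation(idx_all)
        a, b = pick[:n1], pick[n1:]
        r1 = counts[a].sum() / durs[a].sum()
        r2 = counts[b].sum() / durs[b].sum()
        if r1 + r2 == 0:
            scores[s] = np.nan
        else:
            scores[s] = abs(r1 - r2) / (r1 + r2)
    return scores


def trajectory_remapping(map_h1: RateMap1D, map_h2: RateMap1D,
                         binned: BinnedTrajectory1D | None = None,
                         flights_by_human: dict | None = None,
                         spike_times=None, n_shuffles: int = 1000,
                         seed=0) -> RemapMetrics:
    """Empirical 1D remapping metrics, plus the score null when the flight
    partition is provided."""
    r, dist = map_metrics_1d(map_h1, map_h2)
    score = remapping_score(map_h1.mean_rate, map_h2.mean_rate)
    null_score = np.empty(0)
    if flights_by_human is not None and spike_times is not None:
        null_score = null_trial_shuffle(binned, flights_by_human, spike_times,
                                        n_shuffles, seed)
    return RemapMetrics(r, dist, score, null_score=null_score)


# ---------------------------------------------------------------------------
# 2D contexts
# ---------------------------------------------------------------------------

@dataclass
class ContextPair:
    context_ids: tuple
    map_a: RateMap2D
    map_b: RateMap2D
    shared_fraction: float
    spikes_a: int
    spikes_b: int
    metrics: RemapMetrics | None = None


def context_pair_metrics(map_a: RateMap2D, map_b: RateMap2D,
                         min_shared_fraction: float = 0.3,
                         min_spikes: int = 20) -> ContextPair | None:
    """Check the context-pair inclusion rules and compute 2D metrics.

    Shared fraction = |valid_a & valid_b| / |valid_a | valid_b|; each
    context needs at least ``min_spikes`` spikes.  Returns None when the
    pair is not analyzable.
    """
    inter = int((map_a.valid & map_b.valid).sum())
    union = int((map_a.valid | map_b.valid).sum())
    shared = inter / union if union else 0.0
    na, nb = int(map_a.spike_count.sum()), int(map_b.spike_count.sum())
    pair = ContextPair(("A", "B"), map_a, map_b, shared, na, nb)
    if shared < min_shared_fraction or min(na, nb) < min_spikes:
        return None
    r, dist = map_metrics_2d(map_a, map_b)
    score = remapping_score(map_a.mean_rate, map_b.mean_rate)
    pair.metrics = RemapMetrics(r, dist, score)
    return pair


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def stability_even_odd(linearized, length, spike_times, bin_size=0.15,
                       kernel_taps=7, kernel_sigma=1.0,
                       min_flights: int = 4) -> float:
    """Spearman r between 1D maps built on even- vs odd-indexed flights."""
    if len(linearized) < min_flights:
        raise ValidationError(f"needs at least {min_flights} flights")
    even = [f for i, f in enumerate(linearized) if i % 2 == 0]
    odd = [f for i, f in enumerate(linearized) if i % 2 == 1]
    maps = []
    for half in (even, odd):
        b = BinnedTrajectory1D(half, length, bin_size, kernel_taps, kernel_sigma)
        m = b.rate_map(spike_times)
        if m.spike_count.sum() == 0:
            raise ValidationError("a split half has no spikes")
        maps.append(m)
    common = maps[0].valid & maps[1].valid
    a, b = maps[0].rate[common], maps[1].rate[common]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def temporal_stability_halves(linearized, spike_times, n_shuffles: int = 1000,
                              seed=0):
    """First-half vs second-half mean-rate comparison with a random-split null.

    Uses per-flight mean rates along one trajectory to one human.  Returns
    (empirical |first - second| rate difference, null array from random
    equal-size splits).  A stationary modulation lands inside the null; a
    drifting gain falls outside it.
    """
    if len(linearized) < 4:
        raise ValidationError("needs at least two flights per half")
    spike_times = np.asarray(spike_times, float)
    counts = np.array([np.sum((spike_times >= f.t[0])
                              & (spike_times <= f.t[-1])) for f in linearized])
    durs = np.array([f.t[-1] - f.t[0] for f in linearized])
    rates = counts / durs
    half = len(rates) // 2
    emp = abs(rates[:half].mean() - rates[half:].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    idx = np.arange(len(rates))
    for s in range(n_shuffles):
        pick = rng.permutation(idx)
        null[s] = abs(rates[pick[:half]].mean() - rates[pick[half:]].mean())
    return emp, null
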