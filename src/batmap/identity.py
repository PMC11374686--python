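"""Peri-event window rates and label-permutation tests.

For every flight, firing is summarized as the rate in a 2-s window at
take-off (-1.75 to +0.25 s) or at landing (-0.25 to +1.75 s), half-open on
the right.  At each landing (and/or take-off) location the absolute
difference of mean rates between the two humans (or between
conspecific-present and -absent trials) is compared to a null built by
shuffling the trial labels — exhaustively over distinct label assignments
when few enough, otherwise by random relabeling, capped at 1,000
permutations.  A location is only analyzable when each label has at least
four trials, the windows contain at least 15 spikes with at least four
spiking trials, and the permutation resolution 1/n_distinct is at most 0.02.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .session import Session, SpikeTrain

WINDOWS = {"take_off": (-1.75, 0.25), "landing": (-0.25, 1.75)}


def derive_seed(global_seed: int, *keys) -> int:
    """Stable per-(unit, location, ...) substream seed below 2**31."""
    h = zlib.crc32(repr((int(global_seed),) + tuple(map(str, keys))).encode())
    return int(h % (2 ** 31))


def window_rate(spikes: SpikeTrain, event_time: float,
                event_kind: str = "landing", windows=None) -> float:
    """Spikes in the event window divided by its 2-s length (Hz)."""
    w0, w1 = (windows or WINDOWS)[event_kind]
    n = spikes.count_in(event_time + w0, event_time + w1)
    return n / (w1 - w0)


def window_count(spikes: SpikeTrain, event_time: float,
                 event_kind: str = "landing", windows=None) -> int:
    w0, w1 = (windows or WINDOWS)[event_kind]
    return spikes.count_in(event_time + w0, event_time + w1)


@dataclass
class PermTestResult:
    unit_id: str
    location_id: str | None
    event: str
    analyzable: bool = True
    note: str = ""
    empirical_diff: float = np.nan   # |mean(group1) - mean(group2)|, Hz
    sign: int = 0                    # sign of mean(group1) - mean(group2)
    null_diffs: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: float = np.nan
    n_perm: int = 0
    n1: int = 0
    n2: int = 0
    significant: bool = False
    bonferroni_n: int = 1
    variant: str = "full"            # full / conspecific_excluded / presence


def two_group_permutation(values, in_group1, n_perm_max: int = 1000,
                          seed: int = 0, enumerate_limit: int = 100_000):
    """Absolute mean-difference permutation test for two labeled groups.

    Returns (empirical |diff|, sign, null array, n_distinct).  Permutations
    reassign which trials belong to group 1 (same group sizes); when the
    number of distinct assignments is small they are enumerated and sampled
    without replacement, otherwise assignments are drawn uniformly.
    """
    values = np.asarray(values, float)
    in_group1 = np.asarray(in_group1, bool)
    n, n1 = values.size, int(in_group1.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be nonempty")
    diff = values[in_group1].mean() - values[~in_group1].mean()
    n_distinct = comb(n, n1)
    rng = np.random.default_rng(seed)
    n_perm = min(n_perm_max, n_distinct)
    if n_distinct <= enumerate_limit:
        all_idx = np.fromiter(
            (i for c in combinations(range(n), n1) for i in c),
            int).reshape(n_distinct, n1)
        take = (np.arange(n_distinct) if n_distinct <= n_perm
                else rng.choice(n_distinct, size=n_perm, replace=False))
        idx = all_idx[take]
    else:
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    total = values.sum()
    g1 = values[idx].sum(axis=1)
    null = np.abs(g1 / n1 - (total - g1) / (n - n1))
    return abs(diff), int(np.sign(diff)), null, n_distinct


def _perm_p(empirical: float, null: np.ndarray) -> float:
    return (1 + int(np.sum(null >= empirical))) / (1 + null.size)


def label_permutation_test(rates, labels, counts, unit_id: str,
                           location_id: str | None, event: str,
                           config: AnalysisConfig | None = None,
                           seed: int = 0, bonferroni_n: int = 1,
                           variant: str = "full") -> PermTestResult:
    """Permutation test of mean window-rate difference between two labels.

    ``labels`` carries two distinct values (human ids, or presence flags);
    ``counts`` are the raw spike counts per trial window, used for the
    spike-based inclusion rules.
    """
    cfg = config or AnalysisConfig()
    rates = np.asarray(rates, float)
    labels = np.asarray(labels, object)
    counts = np.asarray(counts, int)
    uniq = sorted(set(labels.tolist()), key=str)
    res = PermTestResult(unit_id, location_id, event, variant=variant,
                         bonferroni_n=bonferroni_n)
    if len(uniq) != 2:
        res.analyzable = False
        res.note = "needs exactly two label values"
        return res
    g1 = labels == uniq[0]
    res.n1, res.n2 = int(g1.sum()), int((~g1).sum())
    if min(res.n1, res.n2) < cfg.min_trials_per_label:
        res.analyzable = False
        res.note = f"fewer than {cfg.min_trials_per_label} trials per label"
        return res
    if counts.sum() < cfg.min_spikes_windows:
        res.analyzable = False
        res.note = f"fewer than {cfg.min_spikes_windows} spikes in windows"
        return res
    if int((counts > 0).sum()) < cfg.min_trials_with_spikes:
        res.analyzable = False
        res.note = f"fewer than {cfg.min_trials_with_spikes} spiking trials"
        return res
    n_distinct = comb(rates.size, res.n1)
    if 1.0 / n_distinct > cfg.max_perm_resolution:
        res.analyzable = False
        res.note = (f"permutation resolution 1/{n_distinct} exceeds "
                    f"{cfg.max_perm_resolution}")
        return res
    emp, sign, null, _ = two_group_permutation(
        rates, g1, cfg.n_shuffles, seed)
    res.empirical_diff, res.sign, res.null_diffs = emp, sign, null
    res.n_perm = null.size
    res.p = _perm_p(emp, null)
    level = 1.0 - cfg.alpha / bonferroni_n
    res.significant = bool(emp > np.quantile(null, level))
    return res


# ---------------------------------------------------------------------------
# trial assembly from a segmented session
# ---------------------------------------------------------------------------

def event_trials(flights, spikes: SpikeTrain,
                 windows=None) -> pd.DataFrame:
    """One row per flight x event with window rate, count and labels."""
    rows = []
    for fid, f in enumerate(flights):
        for event, (loc, t, human) in {
            "take_off": (f.takeoff_location_id, f.start_s, f.human_at_takeoff),
            "landing": (f.landing_location_id, f.end_s, f.human_at_landing),
        }.items():
            if loc is None:
                continue
            rows.append({
                "flight_id": fid, "event": event, "location": loc,
                "event_time": t, "human": human,
                "conspecific_present": f.conspecific_present_at_landing,
                "rate": window_rate(spikes, t, event, windows),
                "count": window_count(spikes, t, event, windows),
            })
    return pd.DataFrame(rows, columns=["flight_id", "event", "location",
                                       "event_time", "human",
                                       "conspecific_present", "rate", "count"])


def identity_permutation_tests(trials: pd.DataFrame, unit_id: str,
                               config: AnalysisConfig | None = None,
                               seed: int = 0, events=("take_off", "landing"),
                               variant: str = "full") -> list:
    """Identity tests at every location x event, Bonferroni over the number
    of analyzable location/event families for the unit."""
    cfg = config or AnalysisConfig()
    trials = trials[trials["human"].notna()]
    groups = [((loc, ev), g) for (loc, ev), g in
              trials.groupby(["location", "event"], sort=True) if ev in events]
    prelim = []
    for (loc, ev), g in groups:
        r = label_permutation_test(
            g["rate"].to_numpy(), g["human"].to_numpy(), g["count"].to_numpy(),
            unit_id, loc, ev, cfg,
            seed=derive_seed(seed, unit_id, loc, ev, variant), variant=variant)
        prelim.append(r)
    n_family = max(sum(r.analyzable for r in prelim), 1)
    for r in prelim:
        if r.analyzable:
            r.bonferroni_n = n_family
            level = 1.0 - cfg.alpha / n_family
            r.significant = bool(r.empirical_diff > np.quantile(r.null_diffs, level))
    return prelim


def conspecific_presence_tests(trials: pd.DataFrame, unit_id: str,
                               config: AnalysisConfig | None = None,
                               seed: int = 0) -> list:
    """Presence/absence tests at each landing location."""
    cfg = config or AnalysisConfig()
    t = trials[(trials["event"] == "landing")
               & trials["conspecific_present"].notna()]
    prelim = []
    for loc, g in t.groupby("location", sort=True):
        labels = np.where(g["conspecific_present"].to_numpy(bool),
                          "present", "absent")
        r = label_permutation_test(
            g["rate"].to_numpy(), labels, g["count"].to_numpy(),
            unit_id, loc, "landing", cfg,
            seed=derive_seed(seed, unit_id, loc, "presence"),
            variant="presence")
        prelim.append(r)
    n_family = max(sum(r.analyzable for r in prelim), 1)
    for r in prelim:
        if r.analyzable:
            r.bonferroni_n = n_family
            level = 1.0 - cfg.alpha / n_family
            r.significant = bool(r.empirical_diff > np.quantile(r.null_diffs, level))
    return prelim


def identity_tests_excluding_conspecific(trials: pd.DataFrame, unit_id: str,
                                         config: AnalysisConfig | None = None,
                                         seed: int = 0) -> list:
    """Identity tests after removing trials with the other bat present at
    the take-off or landing location."""
    present = np.array([bool(v) if v is not None and v == v else False
                        for v in trials["conspecific_present"]])
    present_flights = set(trials.loc[present, "flight_id"])
    restricted = trials[~trials["flight_id"].isin(present_flights)]
    return identity_permutation_tests(restricted, unit_id, config, seed,
                                      variant="conspecific_excluded")


# ---------------------------------------------------------------------------
# reward-quantity metrics
# ---------------------------------------------------------------------------

def baseline_rate(spikes: SpikeTrain, landing_times,
                  window=(-0.25, 1.75)) -> float:
    """Session-wide mean rate excluding the peri-landing windows."""
    t0, t1 = spikes.session_span
    total = t1 - t0
    excluded = 0.0
    n_excl = 0
    for t in landing_times:
        a, b = max(t + window[0], t0), min(t + window[1], t1)
        if b > a:
            excluded += b - a
            n_excl += spikes.count_in(a, b)
    remaining = total - excluded
    if remaining <= 0:
        return np.nan
    return (spikes.n_spikes - n_excl) / remaining


def reward_metrics(spikes: SpikeTrain, trials: pd.DataFrame,
                   config: AnalysisConfig | None = None,
                   psth_bin_s: float = 0.25) -> dict:
    """Peri-landing rate changes relative to baseline, and the Spearman
    correlation of the two humans' average peri-landing rate vectors.

    Peak change: max PSTH rate in the (-0.25, +1.75) landing window divided
    by the baseline rate.  Mean change: mean rate in (0, +1.75) divided by
    baseline.  Inclusion per (location, human): >=4 spiking trials and
    >=15 spikes.
    """
    cfg = config or AnalysisConfig()
    t = trials[(trials["event"] == "landing") & trials["human"].notna()]
    base = baseline_rate(spikes, t["event_time"], cfg.landing_window)
    out = {"baseline_hz": base, "per_location": {}, "spearman_r": np.nan,
           "analyzable": False}
    if not np.isfinite(base) or base <= 0:
        out["note"] = "baseline rate undefined or zero"
        return out
    w0, w1 = cfg.landing_window
    edges = np.arange(w0, w1 + 1e-9, psth_bin_s)
    vec = {}
    for (loc, human), g in t.groupby(["location", "human"], sort=True):
        if (g["count"] > 0).sum() < cfg.min_trials_with_spikes or \
                g["count"].sum() < cfg.min_spikes_windows:
            continue
        psth = np.zeros(edges.size - 1)
        post = []
        for et in g["event_time"]:
            rel = spikes.spike_times[
                (spikes.spike_times >= et + w0)
                & (spikes.spike_times < et + w1)] - et
            psth += np.histogram(rel, bins=edges)[0]
            post.append(spikes.count_in(et, et + w1) / w1)
        psth /= len(g) * psth_bin_s
        out["per_location"].setdefault(loc, {})[human] = {
            "peak_rate_change": float(psth.max() / base),
            "mean_rate_change": float(np.mean(post) / base),
            "psth": psth,
        }
        vec.setdefault(human, {})[loc] = psth
    humans = sorted(vec)
    if len(humans) == 2:
        shared = sorted(set(vec[humans[0]]) & set(vec[humans[1]]))
        if shared:
            a = np.concatenate([vec[humans[0]][l] for l in shared])
            b = np.concatenate([vec[humans[1]][l] for l in shared])
            if np.std(a) > 0 and np.std(b) > 0:
                out["spearman_r"] = float(stats.spearmanr(a, b).statistic)
                out["analyzable"] = True
    return out
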