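"""Skaggs spatial information and circular-shift shuffle significance.

Spatial information per spike, summed over valid bins::

    SI = sum_i (p_i * lam_i / lam) * log2(lam_i / lam)    [bits/spike]

where ``p_i`` is the probability of occupying bin i, ``lam_i`` the firing
rate in that bin and ``lam`` the occupancy-weighted mean rate.  Bins with
zero rate contribute zero (the x*log x -> 0 limit).

Significance is assessed against a null built by circularly shifting the
spike train relative to behavior on the concatenated included timeline
(rest removed for self-motion frames; between-traverse periods removed for
the human frame), rebuilding the map and recomputing SI 1,000 times.  A
unit is significant when its empirical SI exceeds the 95th percentile of
its null, Bonferroni-corrected for the number of maps examined per neuron.
Normalized SI is the empirical value divided by the null mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ratemaps import meets_1d_inclusion
from .session import ValidationError


def skaggs_information(p, lam) -> float:
    """SI (bits/spike) from occupancy probabilities and bin rates.

    Accepts 1D arrays over valid bins, or a stack ``lam`` of shape (S, n)
    against shared ``p`` (returns an (S,) vector).
    """
    p = np.asarray(p, float)
    lam = np.asarray(lam, float)
    lam = np.where(np.isfinite(lam), lam, 0.0)
    mean = (p * lam).sum(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        if lam.ndim == 1:
            raise ValidationError("mean rate is zero; SI undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mean > 0, lam / mean, 0.0)
        term = np.where(ratio > 0, p * ratio * np.log2(ratio), 0.0)
    si = term.sum(axis=-1)
    return float(si) if si.ndim == 0 else si


def spatial_information(ratemap) -> float:
    """SI of a built rate map (2D or 1D), over its valid bins."""
    return skaggs_information(ratemap.p, ratemap.rate[ratemap.valid])


def circular_shift_null(binned, spike_times, n_shuffles: int = 1000,
                        seed=0, min_shift_s: float = 1.0) -> np.ndarray:
    """Null SI values from circular spike-train shifts on the timeline.

    ``binned`` is a :class:`BinnedBehavior2D` or :class:`BinnedTrajectory1D`;
    its occupancy, validity and bin geometry are fixed, only the spike bins
    move.  Every shuffle preserves the spike count exactly.
    """
    T = binned.timeline.total
    if T <= 2 * min_shift_s:
        raise ValidationError("timeline too short for circular shifts")
    rng = np.random.default_rng(seed)
    tc = binned.timeline.spikes_concat(spike_times)
    offsets = rng.uniform(min_shift_s, T - min_shift_s, size=n_shuffles)
    if tc.size == 0:
        return np.zeros(n_shuffles)
    shifted = (tc[None, :] + offsets[:, None]) % T
    rates = binned.rate_stack(shifted)          # (S, n_valid)
    return skaggs_information(binned.p_valid, rates)


def test_significance(empirical: float, null: np.ndarray, alpha: float = 0.05,
                      bonferroni_n: int = 1, criterion: str = "percentile"):
    """(p, significant) against a shuffle null.

    p uses the (1 + #{null >= empirical}) / (1 + n) convention; significance
    compares the empirical value to the upper (1 - alpha/bonferroni_n)
    bound of the null (its percentile by default, or mean + z*sd).
    """
    null = np.asarray(null, float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    if bonferroni_n < 1:
        raise ValueError("bonferroni_n must be >= 1")
    p = (1 + int(np.sum(null >= empirical))) / (1 + null.size)
    level = 1.0 - alpha / bonferroni_n
    if criterion == "percentile":
        bound = float(np.quantile(null, level))
    elif criterion == "normal":
        bound = float(null.mean() + stats.norm.ppf(level) * null.std(ddof=1))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return p, bool(empirical > bound)


def normalized_si(empirical: float, null: np.ndarray) -> float:
    m = float(np.mean(null))
    return empirical / m if m > 0 else np.nan


@dataclass
class SIResult:
    unit_id: str
    frame: str                  # self_2d / self_1d / conspecific_1d / human_2d_pooled / human_2d_identity
    key: object = None          # trajectory id or human id, where applicable
    analyzable: bool = True
    note: str = ""
    empirical_si: float = np.nan
    null_si: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float = np.nan
    significant: bool = False
    bonferroni_n: int = 1
    normalized_si: float = np.nan

    @property
    def null_mean(self) -> float:
        return float(self.null_si.mean()) if self.null_si.size else np.nan


def si_test(binned, spike_times, unit_id: str, frame: str, key=None,
            n_shuffles: int = 1000, seed=0, alpha: float = 0.05,
            bonferroni_n: int = 1, min_shift_s: float = 1.0,
            criterion: str = "percentile") -> SIResult:
    """Empirical SI + circular-shift null + significance for one map."""
    emp_map = binned.rate_map(spike_times)
    if emp_map.mean_rate <= 0:
        return SIResult(unit_id, frame, key, analyzable=False,
                        note="zero mean rate on included behavior")
    emp = spatial_information(emp_map)
    null = circular_shift_null(binned, spike_times, n_shuffles, seed, min_shift_s)
    p, sig = test_significance(emp, null, alpha, bonferroni_n, criterion)
    return SIResult(unit_id, frame, key, True, "", emp, null, p, sig,
                    bonferroni_n, normalized_si(emp, null))


def _spikes_per_span(spike_train, spans):
    return [spike_train.count_in(a, b) for (a, b) in spans]


def si_by_frame(frames, unit, frame: str, seed: int = 0,
                exclude_conspecific_flight: bool = False) -> list:
    """SI tests for one unit in one reference frame.

    ``frames`` is a :class:`~batmap.frames.SessionFrames`; ``unit`` a
    :class:`~batmap.session.UnitRecord`.  Returns a list of
    :class:`SIResult` (one per trajectory for 1D frames, one per human for
    the identity frame), including not-analyzable records so denominators
    can be reported.
    """
    from .identity import derive_seed

    cfg = frames.config
    ses = frames.session
    train = unit.spike_train
    uid = unit.unit_id
    results = []

    if frame == "self_2d":
        bat = ses.recorded_bat
        eps = frames.flights[bat]
        counts = _spikes_per_span(train, [(f.start_s, f.end_s) for f in eps])
        if unit.mean_rate < cfg.min_rate_2d:
            return [SIResult(uid, frame, analyzable=False,
                             note=f"mean rate below {cfg.min_rate_2d} Hz")]
        if len(eps) < cfg.min_flights_2d:
            return [SIResult(uid, frame, analyzable=False,
                             note=f"fewer than {cfg.min_flights_2d} flights")]
        if sum(c >= 5 for c in counts) < cfg.min_flights_with_5spikes_2d:
            return [SIResult(uid, frame, analyzable=False,
                             note="too few flights with >=5 spikes")]
        binned = frames.self_2d_binned()
        return [si_test(binned, train.spike_times, uid, frame,
                        n_shuffles=cfg.n_shuffles,
                        seed=derive_seed(seed, uid, frame),
                        alpha=cfg.alpha, min_shift_s=cfg.min_shift_s,
                        criterion=cfg.null_criterion)]

    if frame in ("self_1d", "conspecific_1d"):
        bat = ses.recorded_bat if frame == "self_1d" else ses.conspecific
        if bat is None:
            return [SIResult(uid, frame, analyzable=False,
                             note="no conspecific in session")]
        allowed = (frames.conspecific_rest_flights()
                   if frame == "conspecific_1d" else None)
        prelim = []
        for cid, cluster in enumerate(frames.clusters[bat]):
            members = cluster.member_ids if allowed is None else allowed.get(cid, [])
            binned = (frames.trajectory_binned(bat, cid, members)
                      if members else None)
            ok = (binned is not None
                  and meets_1d_inclusion(binned.flights, train,
                                         cfg.min_flights_1d,
                                         cfg.min_flights_with_spikes_1d,
                                         cfg.min_spikes_1d))
            prelim.append((cid, binned if ok else None))
        n_traj = sum(1 for _, b in prelim if b is not None)
        for cid, binned in prelim:
            if binned is None:
                results.append(SIResult(uid, frame, key=cid, analyzable=False,
                                        note="1D inclusion rules not met"))
            else:
                results.append(si_test(
                    binned, train.spike_times, uid, frame, key=cid,
                    n_shuffles=cfg.n_shuffles,
                    seed=derive_seed(seed, uid, frame, cid), alpha=cfg.alpha,
                    bonferroni_n=max(n_traj, 1), min_shift_s=cfg.min_shift_s,
                    criterion=cfg.null_criterion))
        return results

    if frame in ("human_2d_pooled", "human_2d_identity"):
        humans = ([None] if frame == "human_2d_pooled"
                  else sorted(ses.humans))
        prelim = []
        for h in humans:
            spans_all = frames.traverse_spans(h)
            # group included spans back into their traverse epochs
            eps = [ep for ep in frames.traverses
                   if h is None or ep.human_id == h]
            per_tr = []
            for ep in eps:
                sub = [(a, b) for _, a, b in spans_all
                       if a >= ep.start_s and b <= ep.end_s]
                per_tr.append(sum(_spikes_per_span(train, sub)))
            n_tr = len(eps)
            ok = (n_tr >= cfg.min_traverses
                  and sum(c > 0 for c in per_tr) >= cfg.min_traverses_with_spikes
                  and sum(per_tr) >= cfg.min_spikes_traverses)
            binned = (frames.human_2d_binned(h, exclude_conspecific_flight)
                      if ok else None)
            prelim.append((h, binned, n_tr))
        n_h = sum(1 for _, b, _ in prelim if b is not None)
        for h, binned, n_tr in prelim:
            key = h
            if binned is None:
                results.append(SIResult(uid, frame, key=key, analyzable=False,
                                        note="traverse inclusion rules not met"))
            else:
                results.append(si_test(
                    binned, train.spike_times, uid, frame, key=key,
                    n_shuffles=cfg.n_shuffles,
                    seed=derive_seed(seed, uid, frame, str(key)),
                    alpha=cfg.alpha,
                    bonferroni_n=max(n_h, 1) if frame == "human_2d_identity" else 1,
                    min_shift_s=cfg.min_shift_s, criterion=cfg.null_criterion))
        return results

    raise ValueError(f"unknown frame {frame!r}")


def preferred_vs_nonpreferred(pairs) -> dict:
    """Paired Wilcoxon signed-rank of normalized SI, preferred vs other human.

    ``pairs`` is a sequence of (preferred, non_preferred) normalized-SI
    values for units significant for exactly one human.  With fewer than
    five pairs only descriptives are returned.
    """
    arr = np.asarray(list(pairs), float)
    out = {"n": int(arr.shape[0])}
    if arr.size:
        out["median_preferred"] = float(np.median(arr[:, 0]))
        out["median_nonpreferred"] = float(np.median(arr[:, 1]))
        out["fraction_preferred_greater"] = float(np.mean(arr[:, 0] > arr[:, 1]))
    if arr.shape[0] < 5:
        out.update(statistic=np.nan, p_value=np.nan,
                   note="n < 5 pairs; descriptive only")
        return out
    diff = arr[:, 0] - arr[:, 1]
    if np.allclose(diff, 0):
        out.update(statistic=0.0, p_value=1.0)
        return out
    res = stats.wilcoxon(arr[:, 0], arr[:, 1], zero_method="wilcox",
                         alternative="two-sided")
    out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    return out
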