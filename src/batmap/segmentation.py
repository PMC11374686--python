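"""Behavioral segmentation: flights, rests and human traverses.

Bat positions are smoothed with a local quadratic regression (1-s window,
i.e. a Savitzky-Golay filter of order 2 on the uniform 100-Hz grid); flight
epochs are the supra-threshold (0.5 m/s) runs of the smoothed speed, with
endpoints extended to where the per-axis velocity has converged to zero
(|v| < 0.05 m/s on every axis, the automated stand-in for endpoint trimming).
Rest is sub-0.4 m/s speed within 2 m of a preferred rest centroid found by
k-means.  Human traverses are segmented on the median-filtered coat-pocket
tag: onset when its speed exceeds 0.4 m/s within 0.1 m of the traverse start,
offset at the first time > 12 s later when speed drops below 0.4 m/s within
0.3 m of the start; traverses that pause below 0.2 m/s mid-walk are discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from sklearn.cluster import KMeans

from .config import AnalysisConfig
from .session import RoomGeometry, Session, TrackedSeries, ValidationError

logger = logging.getLogger("batmap")


@dataclass
class FlightEpoch:
    start_s: float
    end_s: float
    take_off_xyz: np.ndarray
    landing_xyz: np.ndarray
    landing_location_id: str | None = None
    takeoff_location_id: str | None = None
    human_at_landing: str | None = None
    human_at_takeoff: str | None = None
    conspecific_present_at_landing: bool | None = None

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValidationError("flight epoch must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TraverseEpoch:
    start_s: float
    end_s: float
    human_id: str
    action: str = "both"                       # feed / handle / both
    excluded_spans: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def included_mask(self, t: np.ndarray) -> np.ndarray:
        """Samples inside the epoch but outside handling/reward exclusions."""
        m = (t >= self.start_s) & (t < self.end_s)
        for (a, b) in self.excluded_spans:
            m &= ~((t >= a) & (t < b))
        return m


@dataclass
class RestLocation:
    centroid_xyz: np.ndarray
    n_members: int


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_bat_positions(series: TrackedSeries,
                         window_s: float = 1.0) -> TrackedSeries:
    """Local quadratic regression per axis over a centered window."""
    n = series.n
    fs = series.fs
    win = int(round(window_s * fs))
    win += (win + 1) % 2  # odd
    if win > n:
        raise ValidationError("smoothing window longer than series")
    if win < 5:
        return series.replace_xyz(series.xyz.copy())
    sm = savgol_filter(series.xyz, win, polyorder=2, axis=0, mode="interp")
    return series.replace_xyz(sm)


def smooth_human_coat(series: TrackedSeries,
                      window_s: float = 2.0) -> TrackedSeries:
    """Centered moving median (2 s) per axis for the coat-pocket tag."""
    n = series.n
    win = int(round(window_s * series.fs))
    win += (win + 1) % 2
    if win > n:
        raise ValidationError("median window longer than series")
    sm = median_filter(series.xyz, size=(win, 1), mode="nearest")
    return series.replace_xyz(sm)


# ---------------------------------------------------------------------------
# flights
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def segment_flights(series: TrackedSeries, geometry: RoomGeometry | None = None,
                    config: AnalysisConfig | None = None,
                    raw_series: TrackedSeries | None = None) -> list:
    """Segment a smoothed bat series into flight epochs.

    Supra-threshold speed runs separated by less than ``merge_gap_s`` are
    merged; endpoints are then extended outward to the nearest sample where
    every axis velocity is below ``trim_velocity``, capturing the full
    take-off and landing decelerations.  The trim velocity is evaluated on
    a short (0.25-s) quadratic-regression derivative — of ``raw_series``
    when given — because the 1-s analysis smoothing smears the landing
    kink and would delay the convergence-to-zero endpoint.
    """
    cfg = config or AnalysisConfig()
    v = series.velocity()
    speed = np.linalg.norm(v, axis=1)
    runs = _runs(speed > cfg.flight_velocity_threshold)
    if not runs:
        return []
    trim_src = raw_series if raw_series is not None else series
    win = int(round(0.25 * trim_src.fs))
    win += (win + 1) % 2
    if 5 <= win <= trim_src.n:
        v_trim = savgol_filter(trim_src.xyz, win, polyorder=2, deriv=1,
                               delta=1.0 / trim_src.fs, axis=0, mode="interp")
    else:
        v_trim = trim_src.velocity()
    # merge close runs
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if series.t[a] - series.t[merged[-1][1] - 1] < cfg.merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    quiet = np.all(np.abs(v_trim) < cfg.trim_velocity, axis=1)
    epochs = []
    prev_stop = 0
    for a, b in merged:
        qa = np.flatnonzero(quiet[prev_stop:a])
        start = prev_stop + qa[-1] if qa.size else a
        qb = np.flatnonzero(quiet[b:])
        stop = b + qb[0] if qb.size else series.n - 1
        prev_stop = stop
        ep = FlightEpoch(series.t[start], series.t[stop],
                         series.xyz[start].copy(), series.xyz[stop].copy())
        if geometry is not None:
            ep.landing_location_id = geometry.nearest_tripod(
                ep.landing_xyz, cfg.landing_assign_radius)
            ep.takeoff_location_id = geometry.nearest_tripod(
                ep.take_off_xyz, cfg.landing_assign_radius)
        epochs.append(ep)
    return epochs


def flight_mask(series: TrackedSeries, flights) -> np.ndarray:
    m = np.zeros(series.n, dtype=bool)
    for f in flights:
        m |= (series.t >= f.start_s) & (series.t <= f.end_s)
    return m


# ---------------------------------------------------------------------------
# rest
# ---------------------------------------------------------------------------

def detect_rest_locations(series: TrackedSeries, k: int = 2,
                          v_thresh: float = 0.4, seed: int = 0) -> list:
    """k-means on sub-threshold positions; centroids sorted by membership."""
    slow = series.speed() < v_thresh
    if not slow.any():
        raise ValidationError("no sub-threshold samples for rest clustering")
    pts = series.xyz[slow]
    k = min(k, pts.shape[0])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pts)
    counts = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-counts, kind="stable")
    return [RestLocation(km.cluster_centers_[i].copy(), int(counts[i]))
            for i in order]


def rest_mask(series: TrackedSeries, centroid, v_thresh: float = 0.4,
              dist_thresh: float = 2.0) -> np.ndarray:
    """True where speed < v_thresh and distance to the rest centroid < 2 m."""
    d = np.linalg.norm(series.xyz - np.asarray(centroid, float), axis=1)
    return (series.speed() < v_thresh) & (d < dist_thresh)


# ---------------------------------------------------------------------------
# traverses
# ---------------------------------------------------------------------------

def segment_traverses(coat: TrackedSeries, traverse_start,
                      config: AnalysisConfig | None = None,
                      human_id: str | None = None) -> list:
    """Segment human traverses from the smoothed coat-tag series."""
    cfg = config or AnalysisConfig()
    if traverse_start is None:
        raise ValidationError("traverse start position missing from config")
    start_xy = np.asarray(traverse_start, float)[:2]
    speed = coat.speed()
    d_xy = np.linalg.norm(coat.xyz[:, :2] - start_xy, axis=1)
    fast = speed > cfg.traverse_velocity_threshold
    onset_ok = fast & (d_xy < cfg.traverse_start_radius)
    epochs = []
    i = 0
    n = coat.n
    hid = human_id or coat.subject_id
    while i < n:
        idx = np.flatnonzero(onset_ok[i:])
        if not idx.size:
            break
        s = i + idx[0]
        t_start = coat.t[s]
        # end: first sample > 12 s later with sub-threshold speed near start
        after = (coat.t > t_start + cfg.traverse_min_duration)
        done = after & (~fast) & (d_xy < cfg.traverse_end_radius)
        idx_e = np.flatnonzero(done[s:])
        if not idx_e.size:
            logger.info("open traverse at t=%.2f s discarded", t_start)
            break
        e = s + idx_e[0]
        epochs.append(TraverseEpoch(t_start, coat.t[e], hid))
        i = e + 1
    return epochs


def discard_paused_traverses(epochs, coat: TrackedSeries,
                             config: AnalysisConfig | None = None) -> list:
    """Drop traverses whose coat speed dips below 0.2 m/s outside exclusions."""
    cfg = config or AnalysisConfig()
    speed = coat.speed()
    kept = []
    for ep in epochs:
        m = ep.included_mask(coat.t)
        # ignore onset/offset samples, which straddle the 0.4 m/s threshold
        core = m & (coat.t > ep.start_s + 0.5) & (coat.t < ep.end_s - 0.5)
        if np.any(speed[core] < cfg.traverse_abort_velocity):
            logger.info("traverse at t=%.2f s discarded (mid-traverse pause)",
                        ep.start_s)
            continue
        kept.append(ep)
    return kept


def exclude_handling(epoch: TraverseEpoch, hand_event_spans,
                     buffer_s: float = 1.0) -> TraverseEpoch:
    """Attach handling/reward spans, each buffered by 100 positional samples
    (1 s at the nominal 100 Hz) on both sides; overlapping spans merge."""
    spans = []
    for (a, b) in hand_event_spans:
        if b < epoch.start_s or a > epoch.end_s:
            raise ValidationError("handling event outside traverse epoch")
        spans.append((a - buffer_s, b + buffer_s))
    spans.sort()
    merged = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    epoch.excluded_spans = [list(s) for s in merged]
    return epoch


# ---------------------------------------------------------------------------
# conspecific presence
# ---------------------------------------------------------------------------

def conspecific_presence(other_bat: TrackedSeries, tripod_xyz, t_landing: float,
                         dist_thresh: float = 2.0,
                         v_thresh: float = 0.4) -> bool | None:
    """True iff the other bat is within 2 m of the tripod with speed below
    the flight-detection threshold at landing time; None on a tracking gap."""
    if other_bat is None or other_bat.n == 0:
        return None
    if t_landing < other_bat.t[0] or t_landing > other_bat.t[-1]:
        return None
    i = int(np.searchsorted(other_bat.t, t_landing))
    i = min(max(i, 0), other_bat.n - 1)
    if abs(other_bat.t[i] - t_landing) > 0.5:
        return None  # tracking gap: unknown, trial excluded downstream
    d = np.linalg.norm(other_bat.xyz[i] - np.asarray(tripod_xyz, float))
    v = other_bat.speed()[i]
    return bool(d < dist_thresh and v < v_thresh)


# ---------------------------------------------------------------------------
# session-level convenience
# ---------------------------------------------------------------------------

def annotate_flights(session: Session, flights) -> list:
    """Fill human-at-landing/take-off and conspecific presence on epochs."""
    cfg = session.config
    other = session.bats.get(session.conspecific) if session.conspecific else None
    for f in flights:
        if f.landing_location_id is not None:
            f.human_at_landing = session.human_at(f.landing_location_id, f.end_s)
            tripod = session.geometry.tripod_positions[f.landing_location_id]
            if other is not None:
                f.conspecific_present_at_landing = conspecific_presence(
                    other, tripod, f.end_s, cfg.rest_distance_threshold,
                    cfg.rest_velocity_threshold)
        if f.takeoff_location_id is not None:
            f.human_at_takeoff = session.human_at(f.takeoff_location_id, f.start_s)
    return flights


def segment_session(session: Session, bat: str | None = None):
    """Smooth + segment one bat: returns (smoothed series, flights)."""
    bat = bat or session.recorded_bat
    sm = smooth_bat_positions(session.bats[bat], session.config.bat_smooth_window_s)
    flights = segment_flights(sm, session.geometry, session.config,
                              raw_series=session.bats[bat])
    if bat == session.recorded_bat:
        annotate_flights(session, flights)
    return sm, flights
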