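"""Assembly of per-session analysis frames.

Bridges the segmentation layer and the statistical layer: smooths and
segments both bats, clusters flights into trajectories, segments human
traverses with handling/reward exclusions, and exposes binned-behavior
objects for each reference frame in which spatial information is tested:

- ``self_2d``      recorded bat's xy position during its own flights
- ``self_1d``      recorded bat along each linearized flight trajectory
- ``conspecific_1d`` the *other* bat's linearized trajectories, restricted
                    to flights flown while the recorded bat was at rest
- ``human_2d``     the moving human's xy position during traverses (pooled
                    or per identity), restricted to recorded-bat rest and
                    with handling/reward spans excluded

Handling/reward event times are inputs when available; otherwise they are
inferred as the sub-0.2 m/s pauses of the traversing human far from the
traverse start (the feeding/handling stop below the bats), then buffered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .ratemaps import (BinnedBehavior2D, BinnedTrajectory1D, Timeline,
                       linearize_flights)
from .segmentation import (annotate_flights, detect_rest_locations,
                           discard_paused_traverses, exclude_handling,
                           flight_mask, rest_mask, segment_flights,
                           segment_traverses, smooth_bat_positions,
                           smooth_human_coat)
from .session import COAT_TAG, Session, ValidationError
from .trajectories import cluster_flights

logger = logging.getLogger("batmap")


@dataclass
class SessionFrames:
    session: Session
    smoothed: dict                  # bat -> smoothed TrackedSeries
    flights: dict                   # bat -> list of FlightEpoch
    flight_samples: dict            # bat -> list of (t, xyz) per flight
    clusters: dict                  # bat -> list of TrajectoryCluster
    rest_centroid: np.ndarray
    rest_masks: dict                # bat -> bool mask on its series
    coat_smoothed: dict             # human -> smoothed coat TrackedSeries
    traverses: list                 # TraverseEpoch, all humans, time order
    config: AnalysisConfig

    # ---------------- frame builders ----------------

    def self_2d_binned(self) -> BinnedBehavior2D:
        bat = self.session.recorded_bat
        sm = self.smoothed[bat]
        epochs = [(f.start_s, f.end_s) for f in self.flights[bat]]
        cfg = self.config
        return BinnedBehavior2D(Timeline(epochs), sm.t, sm.xyz[:, :2],
                                self.session.geometry.extent, cfg.bin_size,
                                cfg.occupancy_cutoff_bat, cfg.smoothing_sigma_bins)

    def trajectory_binned(self, bat: str, cluster_id: int,
                          member_subset=None) -> BinnedTrajectory1D | None:
        """1D binned behavior for one trajectory cluster of one bat."""
        cfg = self.config
        cluster = self.clusters[bat][cluster_id]
        members = cluster.member_ids if member_subset is None else member_subset
        samples = [self.flight_samples[bat][m] for m in members]
        linearized, length = linearize_flights(samples)
        if not linearized:
            return None
        return BinnedTrajectory1D(linearized, length, cfg.bin_size,
                                  cfg.kernel_1d_taps, cfg.kernel_1d_sigma_bins)

    def conspecific_rest_flights(self, min_rest_fraction: float = 0.95):
        """Conspecific flight ids flown while the recorded bat was at rest."""
        other = self.session.conspecific
        if other is None:
            return {}
        rec = self.smoothed[self.session.recorded_bat]
        rmask = self.rest_masks[self.session.recorded_bat]
        out = {}
        for cid, cluster in enumerate(self.clusters[other]):
            kept = []
            for m in cluster.member_ids:
                t, _ = self.flight_samples[other][m]
                sel = (rec.t >= t[0]) & (rec.t <= t[-1])
                if sel.any() and rmask[sel].mean() >= min_rest_fraction:
                    kept.append(m)
            out[cid] = kept
        return out

    def traverse_spans(self, human: str | None = None,
                       require_rest: bool = True):
        """Included (t0, t1) spans inside traverses for one human or pooled."""
        spans = []
        for ep in self.traverses:
            if human is not None and ep.human_id != human:
                continue
            sub = [(ep.start_s, ep.end_s)]
            for (a, b) in ep.excluded_spans:
                sub = _subtract(sub, (a, b))
            spans.extend((ep.human_id, a, b) for a, b in sub)
        if not require_rest:
            return [(a, b) for _, a, b in spans]
        rec = self.smoothed[self.session.recorded_bat]
        rmask = self.rest_masks[self.session.recorded_bat]
        kept = []
        for h, a, b in spans:
            sel = (rec.t >= a) & (rec.t <= b)
            if sel.any() and rmask[sel].mean() >= 0.95:
                kept.append((h, a, b))
        return kept

    def human_2d_binned(self, human: str | None = None,
                        exclude_conspecific_flight: bool = False
                        ) -> BinnedBehavior2D | None:
        """Binned moving-human position over included traverse spans."""
        cfg = self.config
        spans = self.traverse_spans(human)
        if exclude_conspecific_flight and self.session.conspecific:
            other_flights = [(f.start_s, f.end_s)
                             for f in self.flights[self.session.conspecific]]
            cut = []
            for h, a, b in spans:
                sub = [(a, b)]
                for fa, fb in other_flights:
                    sub = _subtract(sub, (fa, fb))
                cut.extend((h, x, y) for x, y in sub)
            spans = cut
        if not spans:
            return None
        t_parts, xy_parts, epochs = [], [], []
        for h, a, b in spans:
            coat = self.coat_smoothed[h]
            sel = (coat.t >= a) & (coat.t < b)
            if not sel.any():
                continue
            t_parts.append(coat.t[sel])
            xy_parts.append(coat.xyz[sel, :2])
            epochs.append((a, b))
        if not epochs:
            return None
        t = np.concatenate(t_parts)
        xy = np.concatenate(xy_parts)
        order = np.argsort(t, kind="stable")
        try:
            return BinnedBehavior2D(Timeline(epochs), t[order], xy[order],
                                    self.session.geometry.extent, cfg.bin_size,
                                    cfg.occupancy_cutoff_human,
                                    cfg.smoothing_sigma_bins)
        except ValidationError:
            return None

    def traverses_by_human(self):
        out = {}
        for ep in self.traverses:
            out.setdefault(ep.human_id, []).append(ep)
        return out


def _subtract(spans, cut):
    """Remove interval ``cut`` from a list of (a, b) spans."""
    a, b = cut
    out = []
    for (x, y) in spans:
        if b <= x or a >= y:
            out.append((x, y))
            continue
        if x < a:
            out.append((x, a))
        if b < y:
            out.append((b, y))
    return out


def infer_handling_spans(coat, epoch, abort_v: float, start_xy,
                         min_dist: float = 1.5):
    """Sub-threshold pauses far from the traverse start: the feeding stop."""
    sel = (coat.t >= epoch.start_s) & (coat.t < epoch.end_s)
    t = coat.t[sel]
    slow = coat.speed()[sel] < abort_v
    far = np.linalg.norm(coat.xyz[sel, :2] - np.asarray(start_xy)[:2],
                         axis=1) > min_dist
    m = slow & far
    spans = []
    if m.any():
        d = np.diff(m.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        stops = list(np.flatnonzero(d == -1) + 1)
        if m[0]:
            starts.insert(0, 0)
        if m[-1]:
            stops.append(m.size)
        spans = [(t[i], t[j - 1]) for i, j in zip(starts, stops)]
    return spans


def build_frames(session: Session, hand_events: dict | None = None,
                 seed: int = 0) -> SessionFrames:
    """Segment and assemble all analysis frames for one session.

    ``hand_events`` optionally maps traverse index -> list of (t0, t1)
    handling/reward spans; when absent they are inferred from the coat tag.
    """
    cfg = session.config
    smoothed, flights, flight_samples, clusters, rest_masks = {}, {}, {}, {}, {}
    for bat, series in session.bats.items():
        sm = smooth_bat_positions(series, cfg.bat_smooth_window_s)
        smoothed[bat] = sm
        eps = segment_flights(sm, session.geometry, cfg, raw_series=series)
        if bat == session.recorded_bat:
            annotate_flights(session, eps)
        flights[bat] = eps
        samples = []
        for f in eps:
            sel = (sm.t >= f.start_s) & (sm.t <= f.end_s)
            samples.append((sm.t[sel], sm.xyz[sel]))
        flight_samples[bat] = samples
        if eps:
            paths = [xyz for _, xyz in samples]
            labels = [f.human_at_landing for f in eps]
            clusters[bat] = cluster_flights(paths, cfg.linkage_distance,
                                            cfg.linkage_method, labels)
        else:
            clusters[bat] = []
    rec = session.recorded_bat
    rests = detect_rest_locations(smoothed[rec], cfg.n_rest_clusters,
                                  cfg.rest_velocity_threshold, seed)
    centroid = rests[0].centroid_xyz
    for bat in session.bats:
        rest_masks[bat] = rest_mask(smoothed[bat], centroid,
                                    cfg.rest_velocity_threshold,
                                    cfg.rest_distance_threshold) \
            & ~flight_mask(smoothed[bat], flights[bat])
    coat_smoothed, traverses = {}, []
    for human, tags in session.humans.items():
        coat = smooth_human_coat(tags[COAT_TAG], cfg.coat_median_window_s)
        coat_smoothed[human] = coat
        if session.geometry.traverse_start is not None:
            eps = segment_traverses(coat, session.geometry.traverse_start,
                                    cfg, human)
            for k, ep in enumerate(eps):
                spans = (hand_events or {}).get((human, k))
                if spans is None:
                    spans = infer_handling_spans(
                        coat, ep, cfg.traverse_abort_velocity,
                        session.geometry.traverse_start)
                if spans:
                    exclude_handling(ep, spans, cfg.handling_buffer_s)
            eps = discard_paused_traverses(eps, coat, cfg)
            traverses.extend(eps)
    traverses.sort(key=lambda e: e.start_s)
    return SessionFrames(session, smoothed, flights, flight_samples, clusters,
                         centroid, rest_masks, coat_smoothed, traverses, cfg)
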