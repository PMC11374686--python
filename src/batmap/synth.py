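"""Synthetic sessions with the statistical structure the analysis assumes.

The generator emulates the two-part session design: a flight phase in which
two bats fly stereotyped round trips between a preferred rest corner and
tripod-mounted human experimenters who swap tripods every 5 min (pairs of
tripods rotate every 15 min, counterbalanced so each human spends equal
time at each tripod), followed by a traverse phase in which the humans take
turns walking a fixed arced path from the room center to the resting bats,
pausing to feed/handle, and walking back.

Flights follow a quadratic Bezier between the rest corner and the tripod
with a minimum-jerk speed profile (peak 3 m/s); per-flight path jitter
perturbs the Bezier control points.  Tracking noise is smooth (0.3-s
correlation) and windowed to stationary periods so a zero-jitter session
produces bit-repeatable flight shapes.  Humans carry three tags (coat
pocket defines position; hands are offset copies).

Spike trains are inhomogeneous-Poisson samples (thinning) from
``rate(t) = baseline + place-field terms`` in the self, conspecific and
human reference frames, multiplied by identity/presence gains inside the
peri-landing analysis window.  One global seed; per-unit substreams are
derived by counter so adding a unit never changes earlier units' draws.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisConfig
from .session import (BlockEntry, COAT_TAG, RoomGeometry, Session, SpikeTrain,
                      TrackedSeries, UnitRecord, write_session)

FS = 100.0
DT = 1.0 / FS


def default_geometry() -> RoomGeometry:
    return RoomGeometry(
        extent=(5.6, 5.2, 2.5),
        tripod_positions={
            "T1": (2.8, 0.8, 1.3), "T2": (4.8, 2.6, 1.3),
            "T3": (2.8, 4.4, 1.3), "T4": (0.8, 2.6, 1.3),
        },
        traverse_start=(2.8, 2.6, 1.2),
        rest_centroids=[(0.4, 0.4, 2.3), (5.2, 0.4, 2.3)],
    )


@dataclass
class UnitTuning:
    """Ground-truth tuning of one simulated unit."""

    unit_id: str
    baseline_hz: float = 0.5
    self_fields: list = field(default_factory=list)         # (center, width, peak)
    conspecific_fields: list = field(default_factory=list)
    human_fields: dict = field(default_factory=dict)        # human -> [(center, width, peak)]
    identity_gain: dict = field(default_factory=dict)       # (location, human) -> gain
    presence_gain: dict = field(default_factory=dict)       # location -> gain
    coding_class: str = "none"

    def validate(self):
        if self.baseline_hz < 0:
            raise ValueError("baseline rate must be >= 0")
        for fields_ in ([self.self_fields, self.conspecific_fields]
                        + list(self.human_fields.values())):
            for (_, w, peak) in fields_:
                if w <= 0 or peak < 0:
                    raise ValueError("field widths must be > 0, peaks >= 0")
        for g in list(self.identity_gain.values()) + list(self.presence_gain.values()):
            if g <= 0:
                raise ValueError("gains must be > 0")


@dataclass
class GroundTruth:
    """Per-unit recovery flags, consistent with the tuning that made them."""
    unit_id: str
    is_spatial_self: bool
    is_identity_modulated: bool
    identity_locations: list
    is_human_position_tuned: bool
    tuned_humans: list
    is_conspecific_tuned: bool
    coding_class: str

    @classmethod
    def from_tuning(cls, t: UnitTuning) -> "GroundTruth":
        return cls(
            unit_id=t.unit_id,
            is_spatial_self=bool(t.self_fields),
            is_identity_modulated=any(g != 1 for g in t.identity_gain.values()),
            identity_locations=sorted({loc for (loc, h), g in
                                       t.identity_gain.items() if g != 1}),
            is_human_position_tuned=bool(t.human_fields),
            tuned_humans=sorted(t.human_fields),
            is_conspecific_tuned=bool(t.conspecific_fields),
            coding_class=t.coding_class,
        )


@dataclass
class SynthParams:
    """Study conditions for one synthetic session.

    Defaults reproduce the recorded protocol: 18 five-min blocks (~90 min)
    of flights with tripod swaps, ~220 flights per bat, then ~20 traverses
    per human along a fixed arc with a feeding/handling pause.
    """

    n_blocks: int = 18
    block_s: float = 300.0
    tripod_pairs: tuple = (("T1", "T3"), ("T2", "T4"))
    rest_duration_range: tuple = (30.0, 50.0)
    hang_duration_s: float = 3.0
    flight_peak_speed: float = 3.0         # m/s
    curve_lateral: float = 0.8             # m, Bezier control offset
    curve_height: float = 0.6              # m, Bezier control z bump
    path_jitter_m: float = 0.05
    rest_noise_m: float = 0.01
    with_conspecific: bool = True
    conspecific_stay_prob: float = 0.3
    conspecific_stay_range: tuple = (8.0, 15.0)
    n_traverses_per_human: int = 20
    traverse_speed: float = 0.8            # m/s cruise
    traverse_accel: float = 2.5            # m/s^2
    traverse_pause_s: float = 5.0
    inter_traverse_s: float = 8.0
    traverse_jitter_m: float = 0.03
    humans: tuple = ("h1", "h2")
    swap_walk_leg_s: float = 3.0
    units: list = field(default_factory=list)   # list of UnitTuning

    def validate(self):
        if self.path_jitter_m < 0 or self.rest_noise_m < 0:
            raise ValueError("jitter must be >= 0")
        if self.n_blocks % (2 * len(self.tripod_pairs)) and self.n_blocks > 2:
            pass  # balance is exact only for multiples; allowed but uneven
        for u in self.units:
            u.validate()

    @property
    def flight_phase_s(self) -> float:
        return self.n_blocks * self.block_s

    def traverse_phase_s(self) -> float:
        if self.n_traverses_per_human == 0:
            return 0.0
        per = (2 * 4.5 + self.traverse_pause_s + self.inter_traverse_s)
        return 20.0 + 2 * self.n_traverses_per_human * per


# ---------------------------------------------------------------------------
# kinematic primitives
# ---------------------------------------------------------------------------

def _min_jerk_fraction(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _bezier(p0, pc, p1, frac) -> np.ndarray:
    p0, pc, p1 = (np.asarray(p, float) for p in (p0, pc, p1))
    # arc-length parameterization on a fine grid
    u_fine = np.linspace(0, 1, 400)
    pts = ((1 - u_fine)[:, None] ** 2 * p0 + 2 * (u_fine * (1 - u_fine))[:, None] * pc
           + (u_fine[:, None] ** 2) * p1)
    s = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if s[-1] == 0:
        return np.repeat(p0[None, :], len(frac), axis=0)
    u = np.interp(np.asarray(frac) * s[-1], s, u_fine)
    return ((1 - u)[:, None] ** 2 * p0 + 2 * (u * (1 - u))[:, None] * pc
            + (u[:, None] ** 2) * p1)


def _flight_segment(p0, p1, control, peak_speed) -> np.ndarray:
    """Minimum-jerk flight along a quadratic Bezier; returns (n, 3) samples."""
    chord = np.linalg.norm(np.asarray(p1) - np.asarray(p0))
    L = chord * 1.1 + 1e-9
    duration = 1.875 * L / peak_speed
    n = max(int(round(duration * FS)), 4)
    return _bezier(p0, control, p1, _min_jerk_fraction(n))


def _trapezoid_fraction(dist, v, a, n) -> np.ndarray:
    """Normalized distance profile for accelerate-cruise-decelerate walking."""
    t_acc = v / a
    d_acc = 0.5 * a * t_acc ** 2
    if 2 * d_acc >= dist:          # triangular
        t_acc = np.sqrt(dist / a)
        total = 2 * t_acc
        t = np.linspace(0, total, n)
        d = np.where(t < t_acc, 0.5 * a * t ** 2,
                     dist - 0.5 * a * (total - t) ** 2)
    else:
        t_cruise = (dist - 2 * d_acc) / v
        total = 2 * t_acc + t_cruise
        t = np.linspace(0, total, n)
        d = np.where(t < t_acc, 0.5 * a * t ** 2,
                     np.where(t < t_acc + t_cruise,
                              d_acc + v * (t - t_acc),
                              dist - 0.5 * a * (total - t) ** 2))
    return d / dist


def _walk_duration(dist, v, a) -> float:
    t_acc = v / a
    d_acc = 0.5 * a * t_acc ** 2
    if 2 * d_acc >= dist:
        return 2 * np.sqrt(dist / a)
    return 2 * t_acc + (dist - 2 * d_acc) / v


def _smooth_noise(rng, n, sigma_m, corr_samples=30) -> np.ndarray:
    """(n, 3) temporally smooth tracking noise with std sigma_m per axis."""
    if sigma_m == 0 or n == 0:
        return np.zeros((n, 3))
    raw = rng.standard_normal((n, 3))
    sm = gaussian_filter1d(raw, corr_samples, axis=0, mode="reflect")
    std = sm.std(axis=0, keepdims=True)
    std[std == 0] = 1.0
    return sm / std * sigma_m


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class TrueFlight:
    bat: str
    start_s: float
    end_s: float
    origin: str                 # 'rest' or tripod label
    target: str                 # tripod label or 'rest'
    human_at_target: str | None
    conspecific_present: bool | None = None


@dataclass
class TrueTraverse:
    human: str
    start_s: float
    end_s: float
    hand_event_spans: list


@dataclass
class BehaviorBundle:
    session: Session
    flights: dict               # bat -> list of TrueFlight
    traverses: list             # list of TrueTraverse
    rest_corner: np.ndarray
    t: np.ndarray
    flight_phase_end: float


def _build_schedule(params: SynthParams):
    """Counterbalanced block schedule: each 15-min superblock picks the next
    tripod pair and runs the stand/swap/stand pattern; the starting
    orientation alternates between visits to the same pair, so time per
    human per tripod is exactly equal whenever each pair is visited an even
    number of times."""
    h1, h2 = params.humans
    blocks = []
    visits = {}
    for i in range(params.n_blocks):
        j = i // 3
        pair = params.tripod_pairs[j % len(params.tripod_pairs)]
        if i % 3 == 0:
            visits[pair] = visits.get(pair, -1) + 1
        swapped = (i % 3 == 1) ^ (visits[pair] % 2 == 1)
        a, b = (pair[1], pair[0]) if swapped else pair
        blocks.append(BlockEntry(i * params.block_s, (i + 1) * params.block_s,
                                 {h1: a, h2: b}))
    return blocks


def _stationary_envelope(n, moving_spans, t0=0.0, ramp_samples=20):
    env = np.ones(n)
    for (a, b) in moving_spans:
        ia = max(int((a - t0) * FS) - ramp_samples, 0)
        ib = min(int((b - t0) * FS) + ramp_samples, n)
        env[ia:ib] = 0.0
    return gaussian_filter1d(env, ramp_samples, mode="nearest")


def _bat_behavior(params, geometry, rng, rest_corner, is_conspecific):
    """Nominal bat positions on the grid plus true flight epochs."""
    n = int(round((params.flight_phase_s + params.traverse_phase_s()) * FS))
    pos = np.tile(np.asarray(rest_corner, float), (n, 1))
    labels, tripods = geometry.tripod_array()
    tripod_xyz = dict(zip(labels, tripods))
    schedule = _build_schedule(params)
    flights = []
    moving = []
    t_cur = rng.uniform(5.0, 10.0)
    phase_end = params.flight_phase_s
    h_ids = list(params.humans)
    while True:
        t_cur += rng.uniform(*params.rest_duration_range)
        # avoid swap-walk windows at block starts
        rel = t_cur % params.block_s
        if rel < 2 * params.swap_walk_leg_s + 2.0:
            t_cur += 2 * params.swap_walk_leg_s + 2.0 - rel
        if t_cur > phase_end - 20.0:
            break
        block = schedule[min(int(t_cur // params.block_s), len(schedule) - 1)]
        if is_conspecific:
            target_label = labels[rng.integers(len(labels))]
        else:
            target_label = block.assignment[h_ids[rng.integers(len(h_ids))]]
        target = np.asarray(tripod_xyz[target_label], float)
        hang = np.asarray(rest_corner, float)
        jit = params.path_jitter_m
        mid = 0.5 * (hang + target)
        d = target - hang
        perp = np.array([-d[1], d[0], 0.0])
        perp /= max(np.linalg.norm(perp), 1e-9)
        sign = 1.0 if (labels.index(target_label) % 2 == 0) else -1.0
        control = mid + sign * params.curve_lateral * perp + \
            np.array([0, 0, params.curve_height])
        # outbound; per-flight peak speed varies ~10% around the nominal
        c_out = control + rng.normal(0, jit, 3)
        e0 = hang + rng.normal(0, jit / 2, 3)
        e1 = target + rng.normal(0, jit / 2, 3)
        v_out = params.flight_peak_speed * rng.uniform(0.9, 1.1)
        seg = _flight_segment(e0, e1, c_out, v_out)
        i0 = int(round(t_cur * FS))
        i1 = min(i0 + len(seg), n)
        pos[i0:i1] = seg[: i1 - i0]
        t_land = i1 / FS
        human = None
        for b in schedule:
            if b.start_s <= t_land < b.end_s:
                human = next((h for h, l in b.assignment.items()
                              if l == target_label), None)
        flights.append(TrueFlight(("bat2" if is_conspecific else "bat1"),
                                  i0 / FS, t_land, "rest", target_label, human))
        moving.append((i0 / FS, t_land))
        # hang at the tripod
        stay = params.hang_duration_s
        if is_conspecific and rng.random() < params.conspecific_stay_prob:
            stay = rng.uniform(*params.conspecific_stay_range)
        i2 = min(int(round((t_land + stay) * FS)), n)
        pos[i1:i2] = e1
        # return flight
        c_back = control + rng.normal(0, jit, 3)
        e2 = hang + rng.normal(0, jit / 2, 3)
        v_back = params.flight_peak_speed * rng.uniform(0.9, 1.1)
        seg = _flight_segment(e1, e2, c_back, v_back)
        i3 = min(i2 + len(seg), n)
        pos[i2:i3] = seg[: i3 - i2]
        flights.append(TrueFlight(("bat2" if is_conspecific else "bat1"),
                                  i2 / FS, i3 / FS, target_label, "rest", None))
        moving.append((i2 / FS, i3 / FS))
        pos[i3:] = e2
        t_cur = i3 / FS
        # settle the remaining rest at the jittered hang point until next cycle
    env = _stationary_envelope(n, moving)
    pos += _smooth_noise(rng, n, params.rest_noise_m) * env[:, None]
    return pos, flights


def _human_behavior(params, geometry, rng, human, rest_corner):
    """Nominal coat positions for one human plus true traverse epochs."""
    n = int(round((params.flight_phase_s + params.traverse_phase_s()) * FS))
    schedule = _build_schedule(params)
    labels, tripods = geometry.tripod_array()
    tripod_xyz = dict(zip(labels, tripods))
    stand_z = 1.2
    def stand_at(label):
        x, y, _ = tripod_xyz[label]
        return np.array([x, y, stand_z])
    pos = np.zeros((n, 3))
    moving = []
    center = np.asarray(geometry.traverse_start, float)
    # flight phase: stand at the scheduled tripod; walk via an offset waypoint
    cur = stand_at(schedule[0].assignment[human])
    i_cur = 0
    for k, block in enumerate(schedule):
        target = stand_at(block.assignment[human])
        i_blk = int(block.start_s * FS)
        pos[i_cur:i_blk] = cur
        if not np.allclose(target, cur):
            # two min-jerk legs through a waypoint 0.35 m off room center
            off = np.array([0.35, 0.35, 0.0]) * (1 if human == params.humans[0] else -1)
            way = center + off
            t_walk0 = block.start_s
            for leg_from, leg_to in ((cur, way), (way, target)):
                n_leg = int(params.swap_walk_leg_s * FS)
                frac = _min_jerk_fraction(n_leg)
                seg = leg_from + frac[:, None] * (leg_to - leg_from)
                ia = int(round(t_walk0 * FS))
                ib = min(ia + n_leg, n)
                pos[ia:ib] = seg[: ib - ia]
                t_walk0 += params.swap_walk_leg_s
            moving.append((block.start_s, t_walk0))
            i_cur = min(int(round(t_walk0 * FS)), n)
        else:
            i_cur = i_blk
        cur = target
        pos[i_cur:] = cur
    # move to the traverse start region at the end of the flight phase
    phase_end = params.flight_phase_s
    off = np.array([0.35, 0.35, 0.0]) * (1 if human == params.humans[0] else -1)
    way = center + off
    t0 = phase_end
    for leg_from, leg_to, slow in ((cur, way, False), (way, center, True)):
        dist = np.linalg.norm(leg_to - leg_from)
        dur = max(dist / 0.25, 1.0) if slow else params.swap_walk_leg_s
        n_leg = int(dur * FS)
        frac = _min_jerk_fraction(n_leg)
        seg = leg_from + frac[:, None] * (leg_to - leg_from)
        ia = int(round(t0 * FS))
        ib = min(ia + n_leg, n)
        pos[ia:ib] = seg[: ib - ia]
        t0 += dur
        if not slow:
            moving.append((phase_end, t0))
    pos[min(int(round(t0 * FS)), n):] = center
    return pos, moving, n


def _traverse_geometry(geometry, rest_corner):
    """(center, approach point, Bezier control) of the nominal traverse arc."""
    center = np.asarray(geometry.traverse_start, float)
    approach = np.asarray(rest_corner, float).copy()
    approach[2] = 1.2
    approach = approach + (center - approach) * 0.15   # stop just below the bats
    mid = 0.5 * (center + approach)
    d = approach - center
    perp = np.array([-d[1], d[0], 0.0])
    perp /= max(np.linalg.norm(perp), 1e-9)
    control = mid + 1.0 * perp
    return center, approach, control


def traverse_template_point(geometry: RoomGeometry, frac: float = 0.5,
                            rest_corner=None) -> np.ndarray:
    """A point a fraction of the way along the nominal traverse arc."""
    rest = (np.asarray(rest_corner, float) if rest_corner is not None
            else np.asarray(geometry.rest_centroids[0], float))
    center, approach, control = _traverse_geometry(geometry, rest)
    return _bezier(center, control, approach, np.array([frac]))[0]


def _add_traverses(params, geometry, rng, pos_by_human, moving_by_human,
                   rest_corner, n):
    """Schedule alternating traverses for both humans; mutates positions."""
    center, approach, control = _traverse_geometry(geometry, rest_corner)
    traverses = []
    t_cur = params.flight_phase_s + 18.0
    order = []
    for k in range(params.n_traverses_per_human):
        pair = list(params.humans)
        rng.shuffle(pair)
        order.extend(pair)
    for human in order:
        jit = params.traverse_jitter_m
        c = control + rng.normal(0, jit, 3)
        # per-traverse pace variability keeps walk durations incommensurate
        speed = params.traverse_speed * rng.uniform(0.85, 1.15)
        dist = np.linalg.norm(approach - center) * 1.05
        dur = _walk_duration(dist, speed, params.traverse_accel)
        # keep every traverse above the 12-s segmentation minimum
        pause = max(params.traverse_pause_s * rng.uniform(0.8, 1.3),
                    12.8 - 2 * dur)
        n_leg = int(round(dur * FS))
        frac_out = _trapezoid_fraction(dist, speed,
                                       params.traverse_accel, n_leg)
        seg_out = _bezier(center, c, approach, frac_out)
        seg_back = _bezier(approach, c, center, frac_out)
        i0 = int(round(t_cur * FS))
        i1 = min(i0 + n_leg, n)
        pos = pos_by_human[human]
        pos[i0:i1] = seg_out[: i1 - i0]
        t_pause0 = i1 / FS
        i2 = min(int(round((t_pause0 + pause) * FS)), n)
        pos[i1:i2] = approach
        i3 = min(i2 + n_leg, n)
        pos[i2:i3] = seg_back[: i3 - i2]
        pos[i3:] = center
        t_end = i3 / FS
        traverses.append(TrueTraverse(human, i0 / FS, t_end,
                                      [[t_pause0, i2 / FS]]))
        moving_by_human[human].append((i0 / FS, t_end))
        t_cur = t_end + params.inter_traverse_s
        if int(round(t_cur * FS)) >= n - 10:
            break
    return traverses


def generate_behavior(params: SynthParams, seed: int = 0) -> BehaviorBundle:
    """Generate tracked series for two bats and two humans plus true epochs."""
    params.validate()
    geometry = default_geometry()
    rest_corners = [np.asarray(c, float) for c in geometry.rest_centroids]
    n = int(round((params.flight_phase_s + params.traverse_phase_s()) * FS))
    if params.flight_phase_s < 2 * params.block_s * 0 + 60:
        raise ValueError("session too short")
    t = np.arange(n) / FS
    bats = {}
    flights = {}
    rng_b1 = np.random.default_rng([seed, 1])
    pos1, fl1 = _bat_behavior(params, geometry, rng_b1, rest_corners[0], False)
    bats["bat1"] = TrackedSeries("bat1", "tag", t, pos1)
    flights["bat1"] = fl1
    if params.with_conspecific:
        rng_b2 = np.random.default_rng([seed, 2])
        pos2, fl2 = _bat_behavior(params, geometry, rng_b2, rest_corners[0], True)
        bats["bat2"] = TrackedSeries("bat2", "tag", t, pos2)
        flights["bat2"] = fl2
    humans = {}
    pos_by_human, moving_by_human = {}, {}
    for j, human in enumerate(params.humans):
        rng_h = np.random.default_rng([seed, 10 + j])
        pos, moving, _ = _human_behavior(params, geometry, rng_h, human,
                                         rest_corners[0])
        pos_by_human[human] = pos
        moving_by_human[human] = moving
    rng_tr = np.random.default_rng([seed, 20])
    traverses = _add_traverses(params, geometry, rng_tr, pos_by_human,
                               moving_by_human, rest_corners[0], n)
    for j, human in enumerate(params.humans):
        rng_n = np.random.default_rng([seed, 30 + j])
        pos = pos_by_human[human]
        env = _stationary_envelope(n, moving_by_human[human])
        coat = pos + _smooth_noise(rng_n, n, params.rest_noise_m) * env[:, None]
        right = pos + np.array([0.15, 0.0, 0.15]) + _smooth_noise(rng_n, n, 0.02)
        left = pos + np.array([-0.15, 0.0, 0.1]) + _smooth_noise(rng_n, n, 0.02)
        humans[human] = {
            COAT_TAG: TrackedSeries(human, COAT_TAG, t, coat),
            "right_hand": TrackedSeries(human, "right_hand", t, right),
            "left_hand": TrackedSeries(human, "left_hand", t, left),
        }
    session = Session(geometry=geometry, bats=bats, humans=humans, units=[],
                      schedule=_build_schedule(params), recorded_bat="bat1",
                      config=AnalysisConfig())
    # conspecific presence at landing for the recorded bat's flights
    if params.with_conspecific:
        for f in flights["bat1"]:
            if f.target in geometry.tripod_positions:
                present = any(
                    g.target == f.target and g.end_s <= f.end_s
                    and _next_departure(flights["bat2"], g) >= f.end_s
                    for g in flights["bat2"] if g.target != "rest")
                f.conspecific_present = bool(present)
    return BehaviorBundle(session, flights, traverses, rest_corners[0], t,
                          params.flight_phase_s)


def _next_departure(all_flights, arrival: TrueFlight) -> float:
    """Time the conspecific leaves the tripod it arrived at."""
    for g in all_flights:
        if g.start_s >= arrival.end_s and g.origin == arrival.target:
            return g.start_s
    return np.inf


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _field_rate(pos, fields):
    r = np.zeros(pos.shape[0])
    for center, width, peak in fields:
        d2 = ((pos - np.asarray(center, float)) ** 2).sum(axis=1)
        r += peak * np.exp(-0.5 * d2 / width ** 2)
    return r


def rate_on_grid(bundle: BehaviorBundle, tuning: UnitTuning) -> np.ndarray:
    """Instantaneous firing rate (Hz) on the 100-Hz behavior grid."""
    tuning.validate()
    ses = bundle.session
    rate = np.full(bundle.t.size, float(tuning.baseline_hz))
    rate += _field_rate(ses.bats["bat1"].xyz, tuning.self_fields)
    if tuning.conspecific_fields and "bat2" in ses.bats:
        rate += _field_rate(ses.bats["bat2"].xyz, tuning.conspecific_fields)
    for human, fields in tuning.human_fields.items():
        coat = ses.humans[human][COAT_TAG]
        rate += _field_rate(coat.xyz, fields)
    # gain covers the final approach (last 2 s of flight) and the
    # post-landing analysis window (+1.75 s)
    gain = np.ones(bundle.t.size)
    for f in bundle.flights.get("bat1", []):
        if f.target == "rest":
            continue
        g = tuning.identity_gain.get((f.target, f.human_at_target), 1.0)
        if f.conspecific_present:
            g *= tuning.presence_gain.get(f.target, 1.0)
        if g != 1.0:
            i0 = max(int(max(f.start_s, f.end_s - 2.0) * FS), 0)
            i1 = min(int((f.end_s + 1.75) * FS), gain.size)
            gain[i0:i1] *= g
    rate *= gain
    if np.any(rate < 0):
        raise ValueError("negative instantaneous rate")
    return rate


def generate_spikes(bundle: BehaviorBundle, tuning: UnitTuning,
                    seed: int = 0, unit_index: int = 0) -> SpikeTrain:
    """Thinning-based inhomogeneous-Poisson spike train for one unit."""
    rate = rate_on_grid(bundle, tuning)
    rmax = float(rate.max())
    t0, t1 = bundle.t[0], bundle.t[-1]
    rng = np.random.default_rng([seed, 1000 + unit_index])
    if rmax == 0:
        return SpikeTrain(tuning.unit_id, np.empty(0), (t0, t1))
    n_cand = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    keep = rng.random(n_cand) < np.interp(cand, bundle.t, rate) / rmax
    return SpikeTrain(tuning.unit_id, cand[keep], (t0, t1))


def generate_session(params: SynthParams, seed: int = 0):
    """Behavior + spikes for every unit in ``params.units``.

    Returns (Session, BehaviorBundle, {unit_id: GroundTruth}).
    """
    bundle = generate_behavior(params, seed)
    truth = {}
    for i, tuning in enumerate(params.units):
        train = generate_spikes(bundle, tuning, seed, unit_index=i)
        bundle.session.units.append(UnitRecord.from_train(train))
        truth[tuning.unit_id] = GroundTruth.from_tuning(tuning)
    return bundle.session, bundle, truth


def landing_rate_population(kind: str, rng, n_trials_per_cell: int = 10,
                            humans=("h1", "h2"),
                            locations=("T1", "T2", "T3", "T4"),
                            main_effect_hz: float = 2.0,
                            interaction_hz: float = 3.0,
                            noise_hz: float = 0.5):
    """Simulated peri-landing rates with a known coding structure.

    ``kind`` is one of additive / conjunctive / human_only / location_only /
    none.  Main effects add ``main_effect_hz`` for human h1 and/or location
    T2; the conjunctive kind adds ``interaction_hz`` in the single
    (h1, T2) cell.  Returns (rates, human labels, location labels).
    """
    rows_h, rows_l, rates = [], [], []
    for h in humans:
        for loc in locations:
            mu = 3.0
            if kind in ("additive", "human_only") and h == humans[0]:
                mu += main_effect_hz
            if kind in ("additive", "location_only") and loc == locations[1]:
                mu += main_effect_hz
            if kind == "conjunctive" and h == humans[0] and loc == locations[1]:
                mu += interaction_hz
            rates.extend(rng.normal(mu, noise_hz, n_trials_per_cell))
            rows_h.extend([h] * n_trials_per_cell)
            rows_l.extend([loc] * n_trials_per_cell)
    return np.asarray(rates), rows_h, rows_l


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def flight_template_point(geometry: RoomGeometry, tripod: str,
                          frac: float = 0.5,
                          params: SynthParams | None = None) -> np.ndarray:
    """A point a fraction of the way along the nominal rest->tripod path."""
    p = params or SynthParams()
    rest = np.asarray(geometry.rest_centroids[0], float)
    target = np.asarray(geometry.tripod_positions[tripod], float)
    labels, _ = geometry.tripod_array()
    mid = 0.5 * (rest + target)
    d = target - rest
    perp = np.array([-d[1], d[0], 0.0])
    perp /= max(np.linalg.norm(perp), 1e-9)
    sign = 1.0 if (labels.index(tripod) % 2 == 0) else -1.0
    control = mid + sign * p.curve_lateral * perp + \
        np.array([0, 0, p.curve_height])
    return _bezier(rest, control, target, np.array([frac]))[0]


def fixture_units(geometry: RoomGeometry | None = None) -> list:
    """Four canonical unit tunings: null, place, identity-gain, human-position."""
    geom = geometry or default_geometry()
    t3 = np.asarray(geom.tripod_positions["T3"], float)
    mid_flight = flight_template_point(geom, "T3", 0.5)
    mid_traverse = traverse_template_point(geom, 0.5)
    return [
        UnitTuning("null", baseline_hz=1.5),
        UnitTuning("place", baseline_hz=0.3,
                   self_fields=[(mid_flight, 0.5, 8.0)]),
        UnitTuning("identity", baseline_hz=0.8,
                   self_fields=[(t3 + np.array([0, 0, 0.3]), 0.6, 5.0)],
                   identity_gain={("T3", "h1"): 3.0},
                   coding_class="conjunctive"),
        UnitTuning("human_pos", baseline_hz=0.4,
                   human_fields={"h1": [(mid_traverse, 0.35, 10.0)]}),
    ]


def fixture_params(n_blocks: int = 6, n_traverses: int = 10,
                   units=None) -> SynthParams:
    """Desk-scale study conditions used by the fixture suite."""
    return SynthParams(n_blocks=n_blocks, rest_duration_range=(10.0, 18.0),
                       n_traverses_per_human=n_traverses,
                       units=list(units) if units is not None else fixture_units())


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write one desk-scale session with the four canonical units to disk."""
    params = fixture_params()
    session, bundle, truth = generate_session(params, seed)
    out = Path(out_dir)
    write_session(out / "session", session)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({u: asdict(g) for u, g in truth.items()}, fh, indent=1)
    return truth
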