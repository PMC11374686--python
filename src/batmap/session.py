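"""Core data model and session I/O.

A session bundles the tracked 3D positions of up to two bats and exactly two
human experimenters (three tags each: right hand, left hand, coat pocket),
sorted spike trains for each recorded unit, the room geometry (tripods,
traverse start, rest centroids) and the 5-min block schedule that says which
human stood at which tripod.

On-disk formats are plain text: a headered tracking CSV with one row per
(time, subject, tag), one spike-time file per unit, and YAML for geometry,
config and schedule.  Writer -> reader round trips are identity to 1e-6 s.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig

logger = logging.getLogger("batmap")

COAT_TAG = "coat"
HAND_TAGS = ("right_hand", "left_hand")


class ValidationError(ValueError):
    """Input violates a session invariant."""


@dataclass
class RoomGeometry:
    """Room extents (m, z-up, origin at a floor corner) and landmark points."""

    extent: tuple = (5.6, 5.2, 2.5)
    tripod_positions: dict = field(default_factory=dict)   # label -> (x, y, z)
    traverse_start: tuple | None = None
    rest_centroids: list | None = None

    def __post_init__(self):
        if any(e <= 0 for e in self.extent):
            raise ValidationError("room extents must be positive")
        for label, p in self.tripod_positions.items():
            if not self._inside(p):
                raise ValidationError(f"tripod {label!r} outside room extents")
        if self.traverse_start is not None and not self._inside(self.traverse_start):
            raise ValidationError("traverse start outside room extents")

    def _inside(self, p, slack=0.0) -> bool:
        return all(-slack <= c <= e + slack for c, e in zip(p, self.extent))

    def tripod_array(self):
        """(labels, (n,3) array) in a stable label order."""
        labels = sorted(self.tripod_positions)
        return labels, np.asarray([self.tripod_positions[l] for l in labels], float)

    def nearest_tripod(self, xyz, max_dist=None):
        """Label of the closest tripod, or None if farther than max_dist."""
        labels, pos = self.tripod_array()
        if not labels:
            return None
        d = np.linalg.norm(pos - np.asarray(xyz, float), axis=1)
        i = int(np.argmin(d))
        if max_dist is not None and d[i] > max_dist:
            return None
        return labels[i]


@dataclass
class TrackedSeries:
    """Uniformly sampled 3D position stream for one subject/tag at ~100 Hz."""

    subject_id: str
    tag_id: str
    t: np.ndarray           # s, strictly increasing
    xyz: np.ndarray         # (n, 3) m

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.xyz = np.asarray(self.xyz, float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValidationError("xyz must be (n, 3) matching timestamps")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError(
                f"timestamps not strictly increasing for {self.subject_id}/{self.tag_id}")
        if np.isnan(self.xyz).any():
            raise ValidationError("NaN positions after preprocessing")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def fs(self) -> float:
        """Median sampling rate (Hz)."""
        return 1.0 / float(np.median(np.diff(self.t))) if self.n > 1 else 0.0

    def velocity(self) -> np.ndarray:
        """Per-axis velocity (n, 3) by central differences of the positions."""
        if self.n < 2:
            return np.zeros_like(self.xyz)
        return np.gradient(self.xyz, self.t, axis=0)

    def speed(self) -> np.ndarray:
        """Norm of the 3D velocity (m/s)."""
        return np.linalg.norm(self.velocity(), axis=1)

    def replace_xyz(self, xyz) -> "TrackedSeries":
        return TrackedSeries(self.subject_id, self.tag_id, self.t.copy(),
                             np.asarray(xyz, float))

    def interp_at(self, times) -> np.ndarray:
        """Positions linearly interpolated at arbitrary times, (m, 3)."""
        times = np.atleast_1d(np.asarray(times, float))
        return np.column_stack([np.interp(times, self.t, self.xyz[:, k])
                                for k in range(3)])


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one unit on the session clock."""

    unit_id: str
    spike_times: np.ndarray
    session_span: tuple     # (t0, t1) s

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, float)
        t0, t1 = self.session_span
        if t1 <= t0:
            raise ValidationError("session span must have positive duration")
        if self.spike_times.size and not np.all(np.diff(self.spike_times) >= 0):
            self.spike_times = np.sort(self.spike_times)
        if self.spike_times.size and (
                self.spike_times[0] < t0 - 1e-9 or self.spike_times[-1] > t1 + 1e-9):
            raise ValidationError(f"spikes outside session span for {self.unit_id}")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def mean_rate(self) -> float:
        t0, t1 = self.session_span
        return self.n_spikes / (t1 - t0)

    def count_in(self, t0: float, t1: float) -> int:
        """Spikes with t in [t0, t1) (half-open)."""
        return int(np.searchsorted(self.spike_times, t1, "left")
                   - np.searchsorted(self.spike_times, t0, "left"))


def classify_unit(spikes: SpikeTrain, span: float | None = None,
                  threshold_hz: float = 5.0) -> str:
    """'interneuron' iff mean firing rate strictly exceeds threshold (5 Hz)."""
    if span is None:
        span = spikes.session_span[1] - spikes.session_span[0]
    if span <= 0:
        raise ValueError("span must be positive")
    return "interneuron" if spikes.n_spikes / span > threshold_hz else "principal"


@dataclass
class UnitRecord:
    unit_id: str
    spike_train: SpikeTrain
    mean_rate: float = 0.0
    unit_class: str = "principal"

    @classmethod
    def from_train(cls, train: SpikeTrain, threshold_hz: float = 5.0) -> "UnitRecord":
        return cls(train.unit_id, train, train.mean_rate(),
                   classify_unit(train, threshold_hz=threshold_hz))


@dataclass
class BlockEntry:
    """One schedule block: which human stands at which tripod."""
    start_s: float
    end_s: float
    assignment: dict        # human_id -> tripod label


@dataclass
class Session:
    geometry: RoomGeometry
    bats: dict              # subject_id -> TrackedSeries (recorded bat first)
    humans: dict            # human_id -> {tag_id: TrackedSeries}
    units: list             # list of UnitRecord
    schedule: list = field(default_factory=list)    # list of BlockEntry
    recorded_bat: str | None = None
    reward_volumes: dict | None = None              # human_id -> ml
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self):
        if len(self.humans) > 2:
            raise ValidationError("at most two humans per session")
        if len(self.bats) > 2:
            raise ValidationError("at most two bats per session")
        if self.recorded_bat is None and self.bats:
            self.recorded_bat = next(iter(self.bats))

    @property
    def span(self) -> tuple:
        t0 = min(s.t[0] for s in self._all_series())
        t1 = max(s.t[-1] for s in self._all_series())
        return (t0, t1)

    def _all_series(self):
        yield from self.bats.values()
        for tags in self.humans.values():
            yield from tags.values()

    @property
    def recorded_series(self) -> TrackedSeries:
        return self.bats[self.recorded_bat]

    @property
    def conspecific(self) -> str | None:
        others = [b for b in self.bats if b != self.recorded_bat]
        return others[0] if others else None

    def human_position_series(self, human_id: str) -> TrackedSeries:
        """The series that defines 'human position': the coat-pocket tag."""
        return self.humans[human_id][COAT_TAG]

    def human_at(self, tripod_label: str, t: float) -> str | None:
        """Which human stands at a tripod at time t, per the block schedule."""
        for block in self.schedule:
            if block.start_s <= t < block.end_s:
                for human, label in block.assignment.items():
                    if label == tripod_label:
                        return human
        return None


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

TRACKING_COLUMNS = ["time_s", "subject", "tag", "x_m", "y_m", "z_m"]


def write_tracking_csv(path, series_list) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "time_s": np.round(s.t, 6), "subject": s.subject_id, "tag": s.tag_id,
            "x_m": s.xyz[:, 0], "y_m": s.xyz[:, 1], "z_m": s.xyz[:, 2]}))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracking_csv(path):
    """Parse tracking rows into {(subject, tag): TrackedSeries}.

    Rows out of time order within a subject/tag are re-sorted with a warning.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse tracking file {path}: {exc}") from exc
    missing = set(TRACKING_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"tracking file missing columns: {sorted(missing)}")
    bad = df[["time_s", "x_m", "y_m", "z_m"]].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 0-based
        raise ValidationError(f"malformed tracking row at line {line}")
    out = {}
    for (subject, tag), g in df.groupby(["subject", "tag"], sort=True):
        t = g["time_s"].to_numpy(float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            warnings.warn(f"re-sorting shuffled timestamps for {subject}/{tag}")
            order = np.argsort(t, kind="stable")
            g = g.iloc[order]
            t = g["time_s"].to_numpy(float)
            keep = np.concatenate([[True], np.diff(t) > 0])
            g, t = g[keep], t[keep]
        out[(str(subject), str(tag))] = TrackedSeries(
            str(subject), str(tag), t, g[["x_m", "y_m", "z_m"]].to_numpy(float))
    return out


def write_spikes(dirpath, trains) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for train in trains:
        np.savetxt(d / f"{train.unit_id}.txt", train.spike_times, fmt="%.6f")


def read_spikes(dirpath, session_span):
    trains = []
    for f in sorted(Path(dirpath).glob("*.txt")):
        times = np.loadtxt(f, ndmin=1) if f.stat().st_size else np.empty(0)
        trains.append(SpikeTrain(f.stem, times, session_span))
    return trains


def _geometry_to_dict(g: RoomGeometry) -> dict:
    return {
        "extent": list(g.extent),
        "tripod_positions": {k: list(map(float, v)) for k, v in g.tripod_positions.items()},
        "traverse_start": list(map(float, g.traverse_start)) if g.traverse_start else None,
        "rest_centroids": [list(map(float, c)) for c in g.rest_centroids]
        if g.rest_centroids else None,
    }


def _geometry_from_dict(d: dict) -> RoomGeometry:
    return RoomGeometry(
        extent=tuple(d["extent"]),
        tripod_positions={k: tuple(v) for k, v in d.get("tripod_positions", {}).items()},
        traverse_start=tuple(d["traverse_start"]) if d.get("traverse_start") else None,
        rest_centroids=[tuple(c) for c in d["rest_centroids"]]
        if d.get("rest_centroids") else None,
    )


def write_session(dirpath, session: Session) -> None:
    """Write a session as a directory of plain-text files."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    series = list(session.bats.values())
    for tags in session.humans.values():
        series.extend(tags.values())
    write_tracking_csv(d / "tracking.csv", series)
    write_spikes(d / "spikes", [u.spike_train for u in session.units])
    meta = {
        "geometry": _geometry_to_dict(session.geometry),
        "recorded_bat": session.recorded_bat,
        "bats": list(session.bats),
        "humans": list(session.humans),
        "schedule": [{"start_s": float(b.start_s), "end_s": float(b.end_s),
                      "assignment": dict(b.assignment)} for b in session.schedule],
        "reward_volumes": session.reward_volumes,
    }
    with open(d / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    session.config.to_yaml(d / "config.yaml")


def load_session(dirpath, config: AnalysisConfig | None = None) -> Session:
    """Load a session directory written by :func:`write_session`.

    Tracking gaps longer than ``config.gap_interp_max_s`` are reported in the
    QC log; shorter gaps are left to the preprocessing stage.
    """
    d = Path(dirpath)
    with open(d / "session.yaml") as fh:
        meta = yaml.safe_load(fh)
    if config is None:
        cfg_path = d / "config.yaml"
        config = AnalysisConfig.from_yaml(cfg_path) if cfg_path.exists() else AnalysisConfig()
    geometry = _geometry_from_dict(meta["geometry"])
    all_series = read_tracking_csv(d / "tracking.csv")
    known = set(meta["bats"]) | set(meta["humans"])
    for (subject, tag) in all_series:
        if subject not in known:
            raise ValidationError(f"unknown subject id {subject!r} in tracking file")
    bats = {b: s for (b, tag), s in all_series.items() if b in meta["bats"]}
    humans = {}
    for h in meta["humans"]:
        humans[h] = {tag: s for (subj, tag), s in all_series.items() if subj == h}
    for (subject, tag), s in all_series.items():
        gaps = np.diff(s.t)
        n_long = int(np.sum(gaps > config.gap_interp_max_s))
        if n_long:
            logger.warning("QC: %s/%s has %d tracking gaps > %.2f s",
                           subject, tag, n_long, config.gap_interp_max_s)
    span_series = list(bats.values()) + [s for tags in humans.values()
                                         for s in tags.values()]
    t0 = min(s.t[0] for s in span_series)
    t1 = max(s.t[-1] for s in span_series)
    trains = read_spikes(d / "spikes", (t0, t1)) if (d / "spikes").exists() else []
    units = [UnitRecord.from_train(tr, config.interneuron_rate_hz) for tr in trains]
    schedule = [BlockEntry(b["start_s"], b["end_s"], b["assignment"])
                for b in meta.get("schedule", [])]
    return Session(geometry=geometry, bats=bats, humans=humans, units=units,
                   schedule=schedule, recorded_bat=meta.get("recorded_bat"),
                   reward_volumes=meta.get("reward_volumes"), config=config)


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------

def format_fraction(k: int, n: int, integer_percent: bool = False) -> str:
    """Render 'X% (k out of n)' the way population fractions are reported."""
    if n == 0:
        return "n/a"
    pct = 100.0 * k / n
    shown = f"{pct:.0f}%" if integer_percent else f"{pct:.1f}%"
    return f"{shown} ({k} out of {n})"


def write_report_tables(results: pd.DataFrame, path, footer_counts=None) -> None:
    """Write one TSV of per-unit test rows plus an optional fraction footer."""
    results.to_csv(path, sep="\t", index=False)
    if footer_counts:
        with open(path, "a") as fh:
            for name, (k, n) in footer_counts.items():
                fh.write(f"# {name}: {format_fraction(k, n)}\n")
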