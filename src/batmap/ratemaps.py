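"""Occupancy-normalized firing-rate maps, 2D (room) and 1D (trajectory).

Both map kinds follow the same recipe: bin the included behavior (0.15 m
bins), count time (occupancy) and spikes per bin, smooth both maps with a
Gaussian kernel (sigma = 1.5 bins in 2D; a 7-tap window with sigma = 1 bin in
1D) and take their bin-by-bin ratio.  Smoothing is truncated at 3 sigma and
restricted to the valid-bin support so that occupancy never bleeds into
never-visited space.  2D bins with raw occupancy below the cutoff (150 ms
for bat frames, 1 s for the human frame) are invalidated unless they were
visited and touch at least one valid bin in their 8-neighborhood.

The :class:`Timeline` helper concatenates the included epochs into a single
gap-free clock; circular spike-train shifts for shuffle nulls operate on this
concatenated time so that shifted spikes always land on included behavior.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter

from .session import ValidationError


class Timeline:
    """Concatenation of included epochs into one continuous clock."""

    def __init__(self, epochs):
        epochs = [(float(a), float(b)) for a, b in epochs if b > a]
        if not epochs:
            raise ValidationError("timeline needs at least one epoch")
        epochs.sort()
        self.starts = np.array([a for a, _ in epochs])
        self.ends = np.array([b for _, b in epochs])
        self.durations = self.ends - self.starts
        self.offsets = np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])
        self.total = float(self.durations.sum())

    def contains(self, times) -> np.ndarray:
        times = np.asarray(times, float)
        i = np.clip(np.searchsorted(self.starts, times, "right") - 1, 0, None)
        return (times >= self.starts[i]) & (times < self.ends[i])

    def to_concat(self, times) -> np.ndarray:
        """Map session times (must lie inside epochs) to concatenated time."""
        times = np.asarray(times, float)
        i = np.clip(np.searchsorted(self.starts, times, "right") - 1, 0, None)
        return self.offsets[i] + (times - self.starts[i])

    def spikes_concat(self, spike_times) -> np.ndarray:
        spike_times = np.asarray(spike_times, float)
        inside = self.contains(spike_times)
        return self.to_concat(spike_times[inside])


# ---------------------------------------------------------------------------
# map containers
# ---------------------------------------------------------------------------

@dataclass
class RateMap2D:
    bin_size: float
    origin: tuple                 # (x0, y0) of bin (0, 0)
    occupancy: np.ndarray         # raw seconds per bin, (nx, ny)
    spike_count: np.ndarray       # raw counts, (nx, ny)
    rate: np.ndarray              # smoothed Hz, NaN on invalid bins
    valid: np.ndarray             # bool mask
    p: np.ndarray                 # occupancy probability over valid bins (sums to 1)
    mean_rate: float              # occupancy-weighted mean of rate over valid bins

    @property
    def peak_rate(self) -> float:
        r = self.rate[self.valid]
        return float(np.nanmax(r)) if r.size else np.nan

    def center_of_mass(self) -> np.ndarray:
        """Rate-weighted centroid (m) over valid bins."""
        ix, iy = np.nonzero(self.valid)
        w = self.rate[ix, iy]
        if w.sum() <= 0:
            raise ValidationError("center of mass undefined for an all-zero map")
        x = (ix + 0.5) * self.bin_size + self.origin[0]
        y = (iy + 0.5) * self.bin_size + self.origin[1]
        return np.array([np.average(x, weights=w), np.average(y, weights=w)])


@dataclass
class RateMap1D:
    bin_size: float
    length: float                 # trajectory template length (m)
    occupancy: np.ndarray
    spike_count: np.ndarray
    rate: np.ndarray
    valid: np.ndarray
    p: np.ndarray
    mean_rate: float

    @property
    def n_bins(self) -> int:
        return self.occupancy.size

    def peak_bin(self) -> int:
        """Index of the maximum-rate valid bin (smallest index on ties)."""
        r = np.where(self.valid, self.rate, -np.inf)
        return int(np.argmax(r))


# ---------------------------------------------------------------------------
# smoothing kernels
# ---------------------------------------------------------------------------

def _smooth2d(stack: np.ndarray, sigma: float, mask: np.ndarray) -> np.ndarray:
    """Gaussian-smooth (…, nx, ny) arrays over the masked support."""
    a = stack * mask
    sig = (0,) * (a.ndim - 2) + (sigma, sigma)
    return gaussian_filter(a.astype(float), sigma=sig, mode="constant",
                           truncate=3.0)


def gaussian_window(n_taps: int = 7, sigma: float = 1.0) -> np.ndarray:
    x = np.arange(n_taps) - (n_taps - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth1d(stack: np.ndarray, kernel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    a = stack * mask
    return convolve1d(a.astype(float), kernel, axis=-1, mode="constant")


# ---------------------------------------------------------------------------
# 2D maps
# ---------------------------------------------------------------------------

class BinnedBehavior2D:
    """Binned included behavior: fixed across shuffles of one unit's spikes."""

    def __init__(self, timeline: Timeline, t, xy, extent, bin_size=0.15,
                 occupancy_cutoff=0.150, sigma_bins=1.5):
        t = np.asarray(t, float)
        xy = np.asarray(xy, float)
        inside = timeline.contains(t)
        self.timeline = timeline
        self.bin_size = float(bin_size)
        self.sigma = float(sigma_bins)
        self.nx = int(np.ceil(extent[0] / bin_size))
        self.ny = int(np.ceil(extent[1] / bin_size))
        self.origin = (0.0, 0.0)
        tc = timeline.to_concat(t[inside])
        order = np.argsort(tc, kind="stable")
        self.sample_tc = tc[order]
        pts = xy[inside][order]
        ix = np.clip((pts[:, 0] // bin_size).astype(int), 0, self.nx - 1)
        iy = np.clip((pts[:, 1] // bin_size).astype(int), 0, self.ny - 1)
        self.sample_bin = ix * self.ny + iy
        dt = np.diff(self.sample_tc)
        med = np.median(dt) if dt.size else 0.01
        dt = np.concatenate([dt, [med]])
        dt = np.minimum(dt, 5 * med)  # a concat seam is not occupancy
        self.sample_dt = dt
        occ = np.bincount(self.sample_bin, weights=dt,
                          minlength=self.nx * self.ny)
        self.occupancy = occ.reshape(self.nx, self.ny)
        if self.occupancy.sum() <= 0:
            raise ValidationError("zero total occupancy")
        self.valid = valid_mask(self.occupancy, occupancy_cutoff)
        self.occ_smooth = _smooth2d(self.occupancy, self.sigma, self.valid)
        # occupancy probability: mask-renormalized smoothed occupancy
        norm = _smooth2d(np.ones_like(self.occupancy), self.sigma, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.valid, self.occ_smooth / norm, 0.0)
        self.p_valid = p[self.valid] / p[self.valid].sum()

    def spike_bins(self, spike_tc: np.ndarray) -> np.ndarray:
        """Flat bin index of each spike given its concatenated time."""
        i = np.clip(np.searchsorted(self.sample_tc, spike_tc, "right") - 1,
                    0, self.sample_tc.size - 1)
        return self.sample_bin[i]

    def spike_count_map(self, spike_tc: np.ndarray) -> np.ndarray:
        counts = np.bincount(self.spike_bins(spike_tc),
                             minlength=self.nx * self.ny)
        return counts.reshape(self.nx, self.ny)

    def rate_map(self, spike_times: np.ndarray) -> RateMap2D:
        """Rate map from session-clock spike times (spikes outside the
        included epochs are dropped)."""
        counts = self.spike_count_map(self.timeline.spikes_concat(spike_times))
        spk_s = _smooth2d(counts, self.sigma, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.valid & (self.occ_smooth > 0),
                            spk_s / self.occ_smooth, np.nan)
        rate = np.where(self.valid, rate, np.nan)
        lam = float(np.nansum(self.p_valid * rate[self.valid]))
        return RateMap2D(self.bin_size, self.origin, self.occupancy, counts,
                         rate, self.valid, self.p_valid, lam)

    def rate_stack(self, spike_tc_stack: np.ndarray):
        """Vectorized rates over valid bins for (S, n_spikes) shifted spikes.

        Returns (S, n_valid) smoothed rates; the occupancy, validity mask and
        occupancy probabilities are shared across shuffles.
        """
        S = spike_tc_stack.shape[0]
        nbins = self.nx * self.ny
        bins = self.spike_bins(spike_tc_stack.ravel()).reshape(S, -1)
        flat = (np.arange(S)[:, None] * nbins + bins).ravel()
        counts = np.bincount(flat, minlength=S * nbins).astype(float)
        maps = counts.reshape(S, self.nx, self.ny)
        spk_s = _smooth2d(maps, self.sigma, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = spk_s / self.occ_smooth
        return rate[:, self.valid]


def valid_mask(occupancy: np.ndarray, cutoff: float) -> np.ndarray:
    """Bins at/above the occupancy cutoff, plus visited bins that touch at
    least one such bin in their 8-neighborhood."""
    base = occupancy >= cutoff
    padded = np.pad(base, 1)
    neigh = np.zeros_like(base, dtype=int)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == dy == 0:
                continue
            neigh += padded[1 + dx: 1 + dx + base.shape[0],
                            1 + dy: 1 + dy + base.shape[1]]
    rescued = (occupancy > 0) & ~base & (neigh > 0)
    return base | rescued


def build_2d_map(series_t, series_xy, spike_times, epochs, extent,
                 bin_size=0.15, occupancy_cutoff=0.150,
                 sigma_bins=1.5) -> RateMap2D:
    """Occupancy-normalized 2D rate map over the included epochs."""
    timeline = Timeline(epochs)
    binned = BinnedBehavior2D(timeline, series_t, series_xy, extent, bin_size,
                              occupancy_cutoff, sigma_bins)
    return binned.rate_map(spike_times)


# ---------------------------------------------------------------------------
# 1D (linearized trajectory) maps
# ---------------------------------------------------------------------------

@dataclass
class LinearizedFlight:
    """One flight's samples mapped to rescaled arc-length from take-off."""
    flight_id: int
    t: np.ndarray           # session-time samples within the flight
    s: np.ndarray           # rescaled arc-length coordinate (m)
    raw_length: float

    def s_at(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, float), self.t, self.s)


def linearize_flights(flight_samples, template_length: float | None = None):
    """Map flights to a common arc-length axis.

    ``flight_samples`` is a sequence of (t, xyz) arrays, one per flight of
    one trajectory cluster.  Each sample gets its cumulative distance from
    take-off, rescaled so every flight spans [0, template_length] (default:
    the mean raw path length of the cluster).  Zero-length flights are
    excluded with a log entry.
    """
    import logging
    logger = logging.getLogger("batmap")
    prepared, lengths = [], []
    for fid, (t, xyz) in enumerate(flight_samples):
        t = np.asarray(t, float)
        xyz = np.asarray(xyz, float)
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0:
            logger.info("zero-length flight %d excluded from linearization", fid)
            continue
        prepared.append((fid, t, s, s[-1]))
        lengths.append(s[-1])
    if not prepared:
        return [], 0.0
    L = float(template_length) if template_length else float(np.mean(lengths))
    out = [LinearizedFlight(fid, t, s * (L / raw), raw)
           for fid, t, s, raw in prepared]
    return out, L


class BinnedTrajectory1D:
    """Binned 1D occupancy for one trajectory's flights (fixed over shuffles)."""

    def __init__(self, linearized, length, bin_size=0.15,
                 kernel_taps=7, kernel_sigma=1.0):
        self.bin_size = float(bin_size)
        self.length = float(length)
        self.n_bins = max(int(np.ceil(length / bin_size)), 1)
        self.kernel = gaussian_window(kernel_taps, kernel_sigma)
        self.flights = list(linearized)
        self.timeline = Timeline([(f.t[0], f.t[-1] + 1e-9) for f in self.flights])
        sample_t, sample_s = [], []
        occ = np.zeros(self.n_bins)
        for f in self.flights:
            dt = np.diff(f.t)
            med = np.median(dt) if dt.size else 0.01
            dt = np.concatenate([dt, [med]])
            b = np.clip((f.s // bin_size).astype(int), 0, self.n_bins - 1)
            occ += np.bincount(b, weights=dt, minlength=self.n_bins)
            sample_t.append(f.t)
            sample_s.append(f.s)
        self.sample_t = np.concatenate(sample_t)
        self.sample_tc = self.timeline.to_concat(self.sample_t)
        order = np.argsort(self.sample_tc, kind="stable")
        self.sample_tc = self.sample_tc[order]
        sam_s = np.concatenate(sample_s)[order]
        self.sample_bin = np.clip((sam_s // bin_size).astype(int), 0, self.n_bins - 1)
        self.occupancy = occ
        self.valid = occ > 0
        self.occ_smooth = _smooth1d(occ, self.kernel, self.valid)
        norm = _smooth1d(np.ones_like(occ), self.kernel, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.valid, self.occ_smooth / norm, 0.0)
        tot = p[self.valid].sum()
        self.p_valid = p[self.valid] / tot if tot > 0 else p[self.valid]

    def spike_bins(self, spike_tc) -> np.ndarray:
        i = np.clip(np.searchsorted(self.sample_tc, spike_tc, "right") - 1,
                    0, self.sample_tc.size - 1)
        return self.sample_bin[i]

    def rate_map(self, spike_times) -> RateMap1D:
        tc = self.timeline.spikes_concat(spike_times)
        counts = np.bincount(self.spike_bins(tc), minlength=self.n_bins).astype(float)
        spk_s = _smooth1d(counts, self.kernel, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.valid & (self.occ_smooth > 0),
                            spk_s / self.occ_smooth, np.nan)
        lam = float(np.nansum(self.p_valid * rate[self.valid]))
        return RateMap1D(self.bin_size, self.length, self.occupancy, counts,
                         rate, self.valid, self.p_valid, lam)

    def rate_stack(self, spike_tc_stack: np.ndarray) -> np.ndarray:
        S = spike_tc_stack.shape[0]
        bins = self.spike_bins(spike_tc_stack.ravel()).reshape(S, -1)
        flat = (np.arange(S)[:, None] * self.n_bins + bins).ravel()
        counts = np.bincount(flat, minlength=S * self.n_bins).astype(float)
        maps = counts.reshape(S, self.n_bins)
        spk_s = _smooth1d(maps, self.kernel, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = spk_s / self.occ_smooth
        return rate[:, self.valid]


def build_1d_map(linearized, length, spike_times, bin_size=0.15,
                 kernel_taps=7, kernel_sigma=1.0) -> RateMap1D:
    binned = BinnedTrajectory1D(linearized, length, bin_size,
                                kernel_taps, kernel_sigma)
    return binned.rate_map(spike_times)


def meets_1d_inclusion(linearized, spike_train, min_flights=7,
                       min_flights_with_spikes=4, min_spikes=15) -> bool:
    """Trajectory inclusion: >=7 flights, >=4 flights with spikes, >=15 spikes."""
    if len(linearized) < min_flights:
        return False
    per_flight = [spike_train.count_in(f.t[0], f.t[-1]) for f in linearized]
    return (sum(1 for c in per_flight if c > 0) >= min_flights_with_spikes
            and sum(per_flight) >= min_spikes)
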