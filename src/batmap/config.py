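"""Analysis configuration: every threshold used downstream, in one place.

Units are seconds and meters throughout (velocities in m/s, rates in Hz).
Distances quoted in centimeters in lab protocols are stored in meters.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class AnalysisConfig:
    # --- behavioral segmentation ---
    flight_velocity_threshold: float = 0.5   # m/s, flight vs rest
    rest_velocity_threshold: float = 0.4     # m/s, confirmed-rest criterion
    rest_distance_threshold: float = 2.0     # m, distance to preferred rest centroid
    trim_velocity: float = 0.05              # m/s, per-axis endpoint trim criterion
    merge_gap_s: float = 0.3                 # s, merge supra-threshold runs closer than this
    landing_assign_radius: float = 2.0       # m, max tripod distance for landing assignment
    n_rest_clusters: int = 2                 # k for rest-location k-means

    # --- traverse segmentation ---
    traverse_velocity_threshold: float = 0.4  # m/s, coat-tag start/end threshold
    traverse_abort_velocity: float = 0.2      # m/s, mid-traverse pause discard
    traverse_start_radius: float = 0.1        # m, xy distance to traverse start (onset)
    traverse_end_radius: float = 0.3          # m, xy distance to traverse start (offset)
    traverse_min_duration: float = 12.0       # s
    handling_buffer_s: float = 1.0            # s, 100 samples at the nominal 100 Hz

    # --- smoothing / preprocessing ---
    bat_smooth_window_s: float = 1.0          # local quadratic regression window
    coat_median_window_s: float = 2.0         # moving median for the coat tag
    gap_interp_max_s: float = 0.5             # interpolate tracking gaps up to this

    # --- rate maps ---
    bin_size: float = 0.15                    # m, 2D and 1D bins
    smoothing_sigma_bins: float = 1.5         # 2D Gaussian kernel sigma
    occupancy_cutoff_bat: float = 0.150       # s, 2D bin validity (bat frames)
    occupancy_cutoff_human: float = 1.0       # s, 2D bin validity (human frame)
    kernel_1d_taps: int = 7                   # 1D Gaussian window width
    kernel_1d_sigma_bins: float = 1.0         # sigma of the 7-tap window

    # --- shuffles & significance ---
    n_shuffles: int = 1000
    min_shift_s: float = 1.0                  # minimum circular shift offset
    alpha: float = 0.05
    null_criterion: str = "percentile"        # or "normal" (mean + 1.96 sd)
    max_perm_resolution: float = 0.02         # permutation-test inclusion bound

    # --- peri-event windows ---
    takeoff_window: tuple = (-1.75, 0.25)     # s relative to take-off
    landing_window: tuple = (-0.25, 1.75)     # s relative to landing

    # --- inclusion minima ---
    min_rate_2d: float = 0.2                  # Hz, active-cell floor (self 2D)
    min_flights_2d: int = 12
    min_flights_with_5spikes_2d: int = 5
    min_flights_1d: int = 7
    min_flights_with_spikes_1d: int = 4
    min_spikes_1d: int = 15
    min_traverses: int = 6
    min_traverses_with_spikes: int = 4
    min_spikes_traverses: int = 15
    min_trials_per_label: int = 4
    min_trials_with_spikes: int = 4
    min_spikes_windows: int = 15
    min_locations_conjunctive: int = 4
    context_min_shared_fraction: float = 0.3
    context_min_spikes: int = 20

    # --- trajectory clustering ---
    linkage_distance: float = 1.3             # m, midpoint of the 1.2-1.4 m range
    linkage_method: str = "single"
    flight_resample_n: int = 100              # equal-time points for pairwise Pearson r
    min_flights_per_human_pairs: int = 4

    # --- misc ---
    interneuron_rate_hz: float = 5.0          # strict > rule
    conjunctive_strict_interaction: bool = False  # require a main effect for 'conjunctive'
    rng_seed: int = 0

    def validate(self) -> None:
        positive = [
            "flight_velocity_threshold", "rest_velocity_threshold",
            "rest_distance_threshold", "bin_size", "smoothing_sigma_bins",
            "occupancy_cutoff_bat", "occupancy_cutoff_human", "n_shuffles",
            "linkage_distance", "traverse_min_duration", "interneuron_rate_hz",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.max_perm_resolution < 1.0):
            raise ValueError("max_perm_resolution must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["takeoff_window"] = list(self.takeoff_window)
        d["landing_window"] = list(self.landing_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("takeoff_window", "landing_window"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
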