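"""Null calibration of the spatial-information shuffle test.

Simulates homogeneous-Poisson units (no spatial tuning) over one synthetic
flight session and asks how often the circular-shift test flags them — the
empirical type-I rate of the 95th-percentile criterion.  Used both by the
test suite and the acceptance script.
"""
from __future__ import annotations

import numpy as np

from .frames import build_frames
from .spatial_info import (circular_shift_null, spatial_information,
                           test_significance)
from .synth import SynthParams, UnitTuning, generate_behavior, generate_spikes


def null_si_calibration(n_units: int = 1000, seed: int = 0,
                        baseline_hz: float = 1.0, n_shuffles: int = 1000,
                        alpha: float = 0.05) -> dict:
    """Fraction of untuned Poisson units flagged by the 2D SI shuffle test.

    One synthetic session of ~100 flights is generated; each unit is an
    independent constant-rate Poisson spike train over that behavior.
    Returns a dict with ``n_units``, ``n_flagged``, ``fraction_flagged``
    and ``fraction_within_bound`` (units whose empirical SI does not exceed
    their null's upper 95% bound).
    """
    params = SynthParams(n_blocks=4, rest_duration_range=(8.0, 15.0),
                         n_traverses_per_human=0, with_conspecific=False)
    bundle = generate_behavior(params, seed)
    frames = build_frames(bundle.session, seed=seed)
    binned = frames.self_2d_binned()
    n_flagged = 0
    n_done = 0
    for i in range(n_units):
        train = generate_spikes(bundle, UnitTuning(f"null{i}", baseline_hz),
                                seed=seed, unit_index=i)
        emp_map = binned.rate_map(train.spike_times)
        if emp_map.mean_rate <= 0:
            continue
        emp = spatial_information(emp_map)
        null = circular_shift_null(binned, train.spike_times, n_shuffles,
                                   seed=(seed * 100003 + i) % (2 ** 31))
        _, sig = test_significance(emp, null, alpha, 1)
        n_flagged += int(sig)
        n_done += 1
    return {
        "n_units": n_done,
        "n_flights": len(frames.flights[bundle.session.recorded_bat]),
        "n_flagged": n_flagged,
        "fraction_flagged": n_flagged / max(n_done, 1),
        "fraction_within_bound": 1.0 - n_flagged / max(n_done, 1),
    }
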