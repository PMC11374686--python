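# batmap

Analysis of dorsal-CA1 hippocampal recordings from Egyptian fruit bats
performing a spatial reward task in the presence of two human experimenters.
The package takes tracked 3D positions (bats and humans, ~100 Hz) and sorted
spike trains and quantifies how neural activity depends on the bat's own
position, the position of the other bat, and the position, movement and
identity of the humans — for systems-neuroscience labs analyzing
spatial-coding electrophysiology with resampling statistics, and as a
desk-scale testbed (via its synthetic-session generator) for the statistical
pipeline itself.

## What it computes

**Behavioral segmentation.** Bat positions are smoothed by local quadratic
regression (1-s window); flights are supra-threshold (0.5 m/s) speed epochs
with endpoints extended to where per-axis velocity converges to zero; rest
is sub-0.4 m/s within 2 m of a k-means rest centroid. Human traverses are
segmented on the 2-s median-filtered coat-pocket tag (0.4 m/s onset within
0.1 m of the traverse start; offset >12 s later within 0.3 m), with
handling/reward spans excluded (±100-sample buffer).

**Rate maps and spatial information.** Occupancy-normalized rate maps in
0.15-m bins (2D, Gaussian σ = 1.5 bins; 1D along linearized flight
trajectories, 7-tap Gaussian window), and Skaggs spatial information per
spike over valid bins:

    SI = Σᵢ (pᵢ λᵢ / λ) · log₂(λᵢ / λ)   [bits/spike]

with significance from 1,000 circular spike-train shifts on the concatenated
included timeline (rest removed), against the null's 95th percentile with
Bonferroni correction, in four reference frames: self (2D and per-trajectory
1D), conspecific position (1D), and human position (2D, pooled and per
identity). Normalized SI = empirical / null mean.

**Identity and presence modulation.** Mean firing-rate differences in 2-s
peri-event windows (take-off −1.75..+0.25 s; landing −0.25..+1.75 s) between
humans (or conspecific present/absent) at each location, tested by label
permutation (exhaustive when few trials permit, capped at 1,000; inclusion
requires ≥4 trials per label, ≥15 window spikes, ≥4 spiking trials, and
permutation resolution ≤ 0.02), plus a variant excluding trials with the
other bat present.

**Conjunctive coding.** A linear model of peri-landing rate with effects-coded
human, location and interaction terms (type-II F tests, p < 0.05) classifies
units as additive / conjunctive / human-only / location-only / none.

**Remapping.** Per-trajectory 1D map pairs across human landing targets:
Pearson correlation, peak distance, and the remapping score
|r₁ − r₂| / (r₁ + r₂), with a trial-label-shuffle null for the score (no
rate remapping) and non-paired-unit nulls for correlation/peak distance
(global remapping); 2D context pairs, and even/odd- and half-session
stability checks.

**Synthetic sessions.** `batmap.synth` generates full sessions — stereotyped
Bezier flights with minimum-jerk kinematics between a rest corner and
tripod-mounted humans who swap tripods every 5 min, arced human traverses
with feeding pauses, and inhomogeneous-Poisson spike trains with
configurable place fields (self / conspecific / human frames) and
identity gains — together with ground truth for recovery tests.

## Worked example

```python
from batmap.synth import fixture_params, generate_session
from batmap.pipeline import run_all

session, bundle, truth = generate_session(fixture_params(), seed=0)
results = run_all(session, seed=0)
print(results["summary"].to_string(index=False))
```

Output (four reference units: untuned, place-tuned, identity-gain at one
tripod, human-position-tuned):

```
                                         category  n_significant  n_analyzable            fraction
                  2D spatial information (flight)              2             3  66.7% (2 out of 3)
            1D spatial information (trajectories)              2             4  50.0% (2 out of 4)
                 conspecific-position information              1             4  25.0% (1 out of 4)
              human-position information (pooled)              1             4  25.0% (1 out of 4)
        human-position information (per identity)              2             4  50.0% (2 out of 4)
           identity-modulated at landing/take-off              1             4  25.0% (1 out of 4)
                   conspecific-presence-modulated              0             4   0.0% (0 out of 4)
        identity-modulated (conspecific excluded)              1             4  25.0% (1 out of 4)
```

The place and identity units carry significant 2D spatial information; the
identity unit is the one identity-modulated unit, it remains significant
after excluding conspecific-present trials, its conjunctive-model class is
`conjunctive`, and the human-position unit is informative for its tuned
human only. Denominators are analyzable units per test family (units
passing that family's inclusion minima).

A command-line interface wraps the same chain:

```
batmap simulate --seed 3 --out demo/
batmap run demo/session --seed 3 --out demo/results/
```

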