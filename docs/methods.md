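# Methods

This note documents the statistical procedures, the synthetic-session model
behind the test suite, and the numerical choices made where the design was
genuinely open. Units are seconds and meters throughout (rates in Hz);
distances quoted in centimeters in lab protocols are stored in meters.

## Preprocessing and segmentation

Bat positions are smoothed per axis by local quadratic regression over a
centered 1-s window (a Savitzky–Golay filter of order 2 on the uniform
100-Hz grid); velocity is the central difference of the smoothed positions.
Flights are runs of speed > 0.5 m/s; runs separated by less than 0.3 s are
merged (sampling noise can split one flight). Endpoints are then extended
outward to the nearest sample where **every** axis velocity is below
0.05 m/s. Because the 1-s regression window smears the landing kink and
delays apparent convergence to zero by several hundred milliseconds, the
trim criterion is evaluated on a short (0.25-s) quadratic-regression
derivative of the raw positions; with this choice, flights in jitter-free
synthetic sessions are recovered with endpoint errors ≤ 0.2 s (≤ 0.5 s with
realistic tracking noise). The trim rule is an automated stand-in for
manual endpoint inspection; both window lengths are configurable.

Rest requires speed < 0.4 m/s within 2 m of the preferred rest centroid
(k-means on sub-threshold positions, k = 2 by default, centroids ordered by
membership), and excludes flight samples so rest and flight epochs are
disjoint by construction.

Human position is defined by the coat-pocket tag (the hand tags move with
reward delivery); it is median-filtered over 2 s. A traverse starts when
coat speed exceeds 0.4 m/s within 0.1 m (xy) of the traverse start point,
and ends at the first time more than 12 s later with speed below 0.4 m/s
within 0.3 m of the start; traverses whose speed dips below 0.2 m/s
mid-walk outside excluded spans are discarded. Handling/reward spans are
buffered by 100 positional samples (1.0 s at the nominal 100 Hz, applied in
time units so irregular sampling is safe) on both sides and excluded from
all human-frame analyses. When explicit handling event times are not
supplied, spans are inferred as the sub-0.2 m/s pauses of the traversing
human more than 1.5 m from the traverse start (the feeding stop below the
bats); real recordings should pass measured event times instead.

## Rate maps

2D maps: positions inside the included epochs are projected to xy and binned
at 0.15 m (grid anchored at the room origin, so maps are reproducible).
Spike-count and occupancy maps are smoothed with a Gaussian kernel
(σ = 1.5 bins, truncated at 3σ) restricted to the valid-bin support, so
occupancy never bleeds into unvisited space, and divided bin by bin.
A bin is valid when its raw occupancy reaches the cutoff (150 ms for bat
frames, 1 s for the human frame) or when it was visited at all and touches
at least one above-cutoff bin in its 8-neighborhood. Occupancy
probabilities p_i are the mask-renormalized smoothed occupancy over valid
bins; the mean rate λ is the p-weighted mean of the bin rates, so
Σ p_i λ_i = λ holds exactly in the information formula.

1D maps: flights of one trajectory cluster are mapped to cumulative
arc-length from take-off and rescaled to the cluster's mean path length, so
the same path flown at different speeds yields the same spatial bins.
Binning at 0.15 m; smoothing with a 7-tap Gaussian window whose σ is 1 bin
(the window width is fixed by design, its σ is an interpretation and is
configurable). A trajectory × unit is analyzable with ≥ 7 flights, ≥ 4
flights with spikes and ≥ 15 spikes.

## Spatial information and shuffle nulls

SI = Σ_i (p_i λ_i / λ) log2(λ_i / λ) bits/spike over valid bins, with
zero-rate bins contributing zero. The null shifts the spike train circularly
on the concatenated included timeline (flight epochs for self frames;
included traverse spans, i.e. with between-traverse periods removed, for the
human frame), rebuilding the map and recomputing SI 1,000 times. Offsets
are uniform with a 1-s minimum to avoid near-identity shifts; every shuffle
preserves the spike count exactly. Significance: empirical SI above the
null's (1 − 0.05/m) quantile, with m the number of maps in the unit's family
(trajectories for 1D frames, humans for the identity frame); a mean + z·SD
criterion is available as a config option. p-values use the (1+k)/(1+n)
convention. Normalized SI divides the empirical value by the null mean.

Frame-specific inclusion: self 2D needs mean rate ≥ 0.2 Hz, ≥ 12 flights
and ≥ 5 flights with ≥ 5 spikes; the human frame needs ≥ 6 traverses, ≥ 4
traverses with spikes and ≥ 15 spikes (per human for the identity split);
conspecific and human frames only use times when the recorded bat is
confirmed at rest (≥ 95% of samples in the span).

## Permutation tests

Peri-event rates are spike counts in half-open 2-s windows divided by 2 s.
The statistic is the absolute difference of group mean rates (sign reported
separately). When the number of distinct label assignments C(n, n1) is at
most 10⁵ they are enumerated and at most 1,000 are sampled without
replacement; otherwise assignments are drawn uniformly. Inclusion requires
≥ 4 trials per label, ≥ 15 spikes across windows, ≥ 4 spiking trials, and
resolution 1/C(n, n1) ≤ 0.02. Bonferroni correction runs over the
location × event families analyzable for the unit. Each unit × location
test derives its RNG substream from the global seed by hashing, so subsets
reproduce. Baseline rate for the reward metrics is the session-wide mean
excluding peri-landing windows (configurable; "baseline" admits several
definitions).

## Conjunctive model

Peri-landing rate ~ C(human, Sum) * C(location, Sum), least squares with
effects coding so main effects are interpretable beside the interaction;
per-term p-values from type-II F tests (each main effect against the model
without it, interaction last; type-II and type-III coincide here for
balanced designs). Classes follow the significance pattern; an interaction
without any main effect maps to `conjunctive` by default (the interaction
governs), with a strict variant behind a flag. With calibrated 5% per-term
tests and essentially full power at the simulated effect sizes (2-Hz main
effects, 3-Hz interaction cell, 0.5-Hz noise, 80 trials), the expected
per-class recovery for single-main-effect classes is 0.95² ≈ 90.3% — errors
are spurious extra terms, not missed effects — which is why the recovery
tests carry a 3-standard-error sampling allowance.

## Remapping

The score |r₁ − r₂| / (r₁ + r₂) on the two conditions' mean rates is
symmetric, scale-invariant and lies in [0, 1]; it is undefined when both
rates are zero. Correlations between maps use bins valid in both; peak ties
break to the smallest bin index; 2D centroids are rate-weighted centers of
mass over valid bins. The score null shuffles human labels across flights
(1,000 shuffles — the construction is fixed by design, the count is ours);
the correlation/peak-distance null pairs maps of different units, one
non-self draw per unit. Temporal stability compares first- vs second-half
mean rates against random equal-size splits.

## Synthetic sessions

The generator reproduces the two-phase session design at configurable scale.
Defaults emulate the recorded protocol: eighteen 5-min blocks (~90 min) in
which two humans stand at a pair of tripods and swap every block (pairs
rotate every 15 min; orientations alternate between visits to a pair, so
occupancy per human per tripod is exactly equal whenever each pair is
visited an even number of times, and near-equal otherwise), with ~220
flights per bat (rest intervals 30–50 s), followed by ~20 traverses per
human along a fixed arced path with a feeding/handling pause. The test
suite and acceptance script run reduced versions (2–6 blocks, shorter rest
intervals, ~50–160 flights) chosen to keep every inclusion rule satisfiable
at desk scale.

Geometry: the room is 5.6 × 5.2 × 2.5 m; four tripods stand at the
mid-walls so every rest-corner → tripod flight is at least ~2.5 m — long
enough that a 1-s smoothing window resolves take-off and landing. Flights
follow a quadratic Bezier (lateral control offset 0.8 m, +0.6 m height)
with a minimum-jerk speed profile, nominal peak 3 m/s varied ±10% per
flight; traverses use a trapezoidal speed profile (cruise 0.8 m/s ± 15%,
2.5 m/s² acceleration) with pause durations jittered and floored so every
traverse exceeds the 12-s segmentation minimum. Pace variability matters
statistically: with identical durations the included spans are commensurate
and a single circular shift can preserve spike–position alignment,
deflating the shuffle null.

Tracking noise is temporally smooth (0.3-s correlation, 1 cm default) and
windowed to stationary periods, so zero-jitter sessions produce exactly
repeatable flight shapes while rest positions wander realistically.

Spikes are inhomogeneous-Poisson samples drawn by thinning from
rate(t) = baseline + Gaussian place-field terms evaluated on the bat's own
position, the conspecific's position, or a human's coat position, all
multiplied by identity/presence gains active from 2 s before landing to
1.75 s after it (covering both the final approach, visible to the 1D maps,
and the peri-landing analysis window). One global seed; per-unit substreams
are indexed by counter so adding a unit never changes earlier units' draws.

What the generator does **not** emulate: RTLS-scale (10–20 cm) tracking
error and dropouts, bursting/theta structure in spiking, crawling along
walls, session-to-session drift, or bats aborting or chaining flights.
Passing recovery tests therefore demonstrates the statistical machinery is
calibrated and sensitive under the protocol's structure, not that real
recordings meet these assumptions.

## Numerical and degenerate-input conventions

Zero-length flights are excluded from linearization with a log entry;
degenerate paths downsample to seven copies of their single point; maps
with zero mean rate, zero total occupancy, or both remapping rates zero are
reported not-analyzable rather than raising mid-pipeline; tracking rows out
of order are re-sorted with a warning and exact-duplicate timestamps
dropped. Trajectory clustering uses single linkage by default (cut at
1.3 m, the midpoint of the 1.2–1.4 m range; average/complete configurable —
the criterion affects cluster counts and is therefore exposed). Flight-pair
correlations resample each flight to 100 equal-time points before
concatenating coordinates; combinatorics are checked as
C(n₁,2) + C(n₂,2) within and n₁·n₂ across.

## Known limitations

The conspecific-presence label depends on a single sample at landing time
(with a 0.5-s gap tolerance); the 2D context-pair analysis uses the top two
configurations by occupancy only; interneuron/principal classification is a
pure rate threshold (> 5 Hz); and the automated handling-span inference is
a geometric heuristic that should be replaced by measured event times
whenever available.
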