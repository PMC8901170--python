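# Methods

This note documents the models and procedures implemented in
`visuomotor`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## ΔF/F drift correction

Raw per-neuron fluorescence is corrected for slow drift by subtracting
a rolling 8th-percentile baseline over a 100 s window and dividing by
the median of the raw trace. A low order statistic tracks the
activity-free floor of the trace because calcium transients are
positive excursions; the 100 s window is long relative to transient
duration (~1 s decay) and short relative to bleaching.

Numerical choices:

- **Window alignment.** Centered by default (no phase lag in the drift
  estimate); a trailing (causal) variant is available. Centered
  windows are forced to an odd sample count so they are symmetric.
- **Edges.** Windows truncate to the available samples; no padding, so
  no invented data.
- **Percentile interpolation.** Linear between order statistics, for
  continuity under small perturbations of the data.
- **Denominator.** The median of the raw trace before baseline
  subtraction. The result is invariant to positive rescaling of the
  raw trace and is reported as a fraction (percent optional).
- A non-positive median raises an error naming the neuron, rather than
  emitting infinities.

## Event-triggered responses

Snippets of ΔF/F around event onsets are averaged per neuron first,
then across neurons (population mean ± SEM across neurons). Events
whose window would cross the recording edge are dropped and counted,
never padded. Scalar onset responses are the mean over a response
window (+0.1 to +1.5 s) minus the mean over a baseline window (−0.3 to
0 s). All windows are half-open, [start, end): the baseline therefore
excludes the onset sample itself, which otherwise contaminates the
baseline with the earliest response frame at 10 Hz sampling.

**Running onsets** are upward crossings of a 10⁻² cm/s speed
threshold. The threshold alone is ill-posed on real (jittery) speed
traces, so crossings must be preceded by ≥1 s below threshold and
followed by ≥1 s above (both configurable). **Session QC** excludes a
session with fewer than three running or mismatch onsets, applied only
to the event kinds a session can contain.

**Suppression index.** Running-onset responses in the closed-loop
condition are transient while dark-condition responses are sustained;
the index is the dark minus closed-loop difference of
baseline-subtracted event-triggered averages over the 2.5–3.5 s
window. Both inputs must share a time axis and baseline window.
Grating responses pool all drift directions into one onset set by
default; a per-direction breakdown is available through the event
attributes.

## Correlation geometry

Per neuron, Pearson correlations of activity with visual flow and with
running speed are computed over the whole open-loop session on the
imaging frame grid, with no smoothing or lag (none is modeled in the
generator either). Zero-variance traces yield NaN correlations with a
`valid` flag rather than being dropped, so neuron indices stay
aligned. The mean pairwise correlation is each neuron's mean Pearson r
with all other neurons (self excluded), averaged over neurons for the
population value.

The **PC angle** is the angle between the leading eigenvector of the
covariance of the mean-subtracted (r_flow, r_run) points and the
r_run (y) axis, reported signed in (−90°, +90°], positive toward
positive r_flow. The eigenvector sign is fixed by requiring a
non-negative y component (non-negative x on ties). The sign convention
is a package convention; the unsigned magnitude is what the geometry
figures of the underlying experiments show. A covariance whose
eigenvalue gap is below 10⁻⁶ of its trace (configurable) raises a
degenerate-geometry error instead of returning an arbitrary axis; at
least three points are required.

Interpretation anchor: populations in which running and flow drives
oppose each other ("opponent") produce scatters elongated along the
negative diagonal (angle near −45°); additively coupled populations
elongate along the positive diagonal (near +45°).

## Synthetic sessions

The generator produces the statistical structure the analyses assume,
at the trace level (no imaging movies, registration, or segmentation).

- **Behavior.** Running is an alternating rest/run renewal process:
  exponential rest durations (mean 60/rate; default rate 3 bouts/min)
  and exponential bout durations (default mean 10 s), with a Gaussian
  speed bump per bout peaking at 15 cm/s. The long-run running
  occupancy has the closed form mean_bout/(mean_bout + mean_rest),
  which the tests check by Monte Carlo. Real mice run with more
  autocorrelated, less stereotyped speed profiles; the bump shape was
  chosen for analytic tractability of occupancy, not realism of speed
  microstructure.
- **Conditions.** Closed loop couples flow = gain × speed exactly;
  mismatches halt flow for 1 s at Poisson-random times (default rate
  2/min), non-overlapping, away from session edges (2 s guard), with
  no requirement that the animal be running at onset — detection-side
  selection is a downstream concern. Open loop draws an independent
  bout-process flow trace as a stand-in for replayed self-generated
  flow (matched statistics, zero coupling); darkness has zero flow;
  grating blocks have uniform 3–8 s stimuli and 2–6 s gray gaps with
  directions sampled from a caller-supplied list (the canonical list
  is taken as an input and not second-guessed).
- **Neurons.** ΔF/F is w_run·speed + w_flow·flow plus impulses at
  mismatch (m_amp) and grating (v_amp) onsets, convolved with a
  single-exponential calcium kernel (default τ = 0.6 s, GCaMP6f-like;
  the kernel is not normalized, so a unit constant drive settles at
  the kernel gain Σexp(−iΔt/τ)), plus additive white Gaussian noise
  (default SD 0.05 ΔF/F). No shot-noise or neuropil model.
- **Archetypes.** `opponent` neurons draw a per-neuron drive magnitude
  (uniform 0.0005–0.012 ΔF/F per cm/s) applied with opposite signs to
  the running and flow channels (±10% imbalance) plus a mismatch
  impulse (0.2–0.6 ΔF/F); `coupled` neurons apply the same magnitude
  with equal signs; `visual` neurons carry flow drive and grating
  impulses with negligible running drive. Sharing the magnitude across
  channels encodes the balanced-opposing-input structure; the spread
  of magnitudes against the fixed noise floor spreads correlation
  radii away from the unit circle, which is what orients the
  correlation scatter along the ±45° diagonals as in real data.
  Archetype counts follow the requested mixture exactly via
  largest-remainder rounding.
- **Determinism.** Every generator takes a seed; identical seeds give
  bit-identical sessions.

Because the generator is linear with white noise, passing recovery
tests demonstrates the estimators' correctness and calibration on data
satisfying their assumptions — not robustness to neuropil
contamination, slow shared states (arousal), nonlinear calcium
indicator dynamics, or non-Poisson event statistics.

## Navigation task

The corridor has fixed width (initial length / 5) and elongating
length. Every four trials the length is multiplied by
clamp(20 s / mean duration of the block, 1, 1.5) and capped at 400% of
the day-1 length; timeout trials (120 s) contribute the timeout
duration to the block mean so the controller sees slow performance.
Trial durations exclude the 5 s gray-screen inter-trial interval.
One perturbation per trial instantaneously offsets the virtual heading
by ±30° (equiprobable sign) when the agent first passes a uniformly
drawn position in 20–80% of the corridor length; an agent that never
reaches that position records no perturbation for that trial.

**Agent.** The agent stands in for the mouse (the experiments have no
behavioral model): it runs in exponential bouts at fixed speed
(defaults 15 units/s, 80% running occupancy), and its *intended*
heading relaxes toward the direction of the corridor-end target at
rate `corrective_gain` (s⁻¹) under white rotational noise
(30°/√s). A perturbation adds its offset to the displayed heading; the
offset decays at the separate rate `perturb_corrective_gain`, the
quantity that grows as animals learn to counter the offsets. Walls
clamp lateral position. Integration is explicit Euler at 0.05 s.

**Performance index.** PI = (Σcosθᵢvᵢ∆t / Σvᵢ∆t) × (time running /
total time), with running defined by the same 10⁻² speed threshold
used for onset detection (one threshold across the package). θ is
measured against the direction from the current position to the
corridor-end center. The generic `performance_index` takes any (x, y)
trajectory and differentiates it; the session-level PI uses ball
motion — virtual heading and treadmill speed — because wall clamping
of the virtual position hides steering error (an agent sliding along a
wall is still mis-aimed) and the treadmill measures ball motion
directly. |PI| ≤ 1 always; an all-stationary trajectory returns PI = 0
with a flag rather than an error.

**Perturbation learning.** Per trial, the turning response is the
cumulative heading change relative to the last pre-perturbation
sample, averaged over +1 to +3 s after the offset (the instantaneous
offset itself is part of the heading record, as it is in the VR). The
epoch metric is mean(left) − mean(right) response; learning is the
late-epoch minus early-epoch metric, by default comparing the first
and last quarters of a session (the experimental comparison is across
training days, which a single simulated session does not have). A
non-correcting agent scores ≈0 (the ±offsets cancel across epochs); an
agent whose offset correction improves scores positive.

## Optogenetic arithmetic

Cycle frequency and duty follow directly from the on/off durations
(1 s/4 s → 0.2 Hz, 20%). Time-averaged power density treats the beam
as a uniform disk at its FWHM diameter and hemisphere alternation as
exact 50/50 time sharing (alternation at 50 Hz is two orders of
magnitude faster than the pulse cycle): 20 mW × 0.2 / 2 / (π·1.5²) ≈
0.283 mW/mm². A Gaussian-beam treatment would not reproduce the
protocol's stated surface density with these parameters; the disk
model does. Depth attenuation is exp(−depth/λ) with λ = 100 µm by
default — the stated upper bound, configurable because only a bound is
established. Puncta positivity counts a cell positive at more than two
puncta and returns the positive fraction.

## Problem sizes

Defaults used by the tests and analysis scripts — 600–900 s sessions
at 10 Hz, 50–100 neurons, 100–200 navigation trials per session — are
the package's standard operating sizes: long enough that session QC
passes with margin and Monte-Carlo checks have tight bands, small
enough to iterate quickly.

## Known limitations

- The generator's linearity means mismatch responses are exactly the
  sum of flow-inhibition release and the impulse; real mismatch
  responses need not decompose additively.
- Open-loop "replay" is statistically matched rather than an actual
  replay of a specific closed-loop episode (a true-replay constructor
  is trivial to add by passing the recorded flow back in).
- The navigation agent has no reward learning; learning-related
  changes are injected by changing its gains between epochs, which is
  sufficient to validate the metrics but says nothing about learning
  dynamics.
- No spike inference, neuropil correction, or motion registration:
  processing starts at the extracted-trace level.
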