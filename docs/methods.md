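# Methods

## Scientific setting

The *E. coli* flagellar motor is driven by membrane-embedded stator
units (MotA/MotB complexes) that bind and unbind dynamically; at high
mechanical load each engaged unit adds a discrete increment of 1–2 Hz to
the rotation rate. Chemoreceptor signaling is classically thought to set
only the motor's direction (CCW/CW bias), but stator recruitment on
ligand exposure also modulates motor *speed*: a sensed-but-not-
metabolized sugar analog (2-deoxy-D-glucose, "2Dg") recruits a unit
transiently — speed rises after a delay of roughly 300 s, stays high for
roughly 200 s, and returns to baseline — while a metabolized sugar
(glucose) sustains recruitment through an elevated proton motive force,
so the speed increase persists. This package implements the complete
quantitative chain used to establish such a result from two assays
(tethered-cell rotation and population swimming), plus fluorescence
quantification, membrane-potential ratios, the chemotactic
drift-velocity implication, and a synthetic-data layer that emulates
both assays with known ground truth so every analysis stage is testable
end to end.

## Tethered-cell analysis

The orientation angle of the rotating cell body is the planar angle of
the vector between the two fitted cell-end positions, unwrapped frame to
frame by adding the multiple of 2π that minimizes the change. The
instantaneous rotation rate is `rate[i] = (θ[i+1] − θ[i])·fps/2π` (Hz,
positive = CCW); rates in the closed band [−0.05, +0.05] Hz are treated
as pauses and excluded from speed and bias statistics. The smoothed rate
is a trailing (causal) moving average over 10 samples; trailing rather
than centered because it is computable online and its alignment does not
affect level estimates, only transition smearing, which the step
detector corrects for (below). CCW bias is the fraction of non-paused
samples with positive rate; pauses are excluded from the denominator as
well (a documented interpretation — the assay description excludes
pauses from speed but is silent on the bias denominator).

### Step detection

Stator engagement/disengagement appears as a discrete change in the
speed level. The detector performs penalized binary segmentation of the
smoothed rate under a piecewise-constant least-squares cost, with a
minimum level dwell (default 10 s) and a penalty scaled from a robust
noise estimate (median-absolute-deviation of rate differences), inflated
by the window length to account for the serial correlation the moving
average introduces. Because a trailing 10-sample average smears a true
step over 10 frames, the least-squares breakpoint of the smoothed trace
sits mid-ramp; each breakpoint is therefore refined by a local
two-segment fit on the *instantaneous* rate, which recovers the exact
transition frame on noiseless input. Segment levels are means of the
instantaneous rate; adjacent levels closer than `min_step` (default
0.5 Hz, rejecting drift while keeping 1–2 Hz single-unit events) are
merged before events are emitted. On noiseless piecewise-constant input
the detector reproduces change points and levels exactly; under the
default 0.05 rad angle noise it recovers 1.5 Hz steps within ±5 s and
±0.2 Hz in ≥ 90% of seeded replicates (measured at 100 replicates).

### Stator number from revolution-time variance

Modeling the rotor as a Poisson stepper — discrete angular steps of
2π/m at exponential waiting times — the time to complete one revolution
(m steps of mean τ) has mean mτ and variance mτ², so
`est_steps_per_rev = mean²/(var·k)` from blocks of k revolutions; a
smoother rotation (smaller variance) implies more steps per revolution
and hence more engaged stator units. Block boundaries are found by
linear interpolation of the unwrapped angle between frames, after
enforcing monotonicity (observation noise can locally reverse the
recorded angle). The conversion from steps per revolution to absolute
stator number requires a steps-per-unit constant that is not
identifiable from these data; `relative_units` is therefore reported
equal to `est_steps_per_rev`, i.e. up to that proportionality constant.
The method-of-moments estimate from a single ~200-revolution trace
carries ~10% sampling SE (variance estimates converge slowly), so
accuracy checks average a few replicate traces. A variance at float
round-off scale is reported as exactly zero (deterministic rotation,
infinite estimated steps).

## Swim-trajectory analysis

Per-frame speed is the displacement magnitude times the frame rate; the
turn angle at an interior frame is the angle between the incoming and
outgoing displacement vectors (zero-displacement frames have undefined
direction and are flagged with angle 0°). A frame is a tumble frame iff
its speed is below half the *track's* mean speed AND its turn angle
exceeds 4° (both criteria at 21 frames/s); consecutive tumble frames —
allowing a single-frame gap, so one sub-threshold frame inside a
reorientation does not split the event — merge into one tumble event.
Runs are the maximal intervals between tumbles (and track ends); runs
shorter than 3 frames are discarded. Tracks lasting ≤ 0.5 s are removed
before analysis to exclude cells crossing the focal plane. Population
statistics average run speeds of all runs whose midpoint falls in a time
bin, reporting SEM and both the number of runs and of distinct cells.

## Fluorescence and membrane potential

Spot intensity is corrected by subtracting the mean of several (default
three) background readings around the cell; negative corrected values
are flagged but never clipped, keeping normalization unbiased.
Normalization divides by the mean of all corrected points strictly
before ligand introduction. No photobleaching correction is applied.
Intensity–speed linearity is assessed by ordinary least squares of
normalized intensity on normalized speed (scipy). Membrane potential is
proxied by the carbocyanine-dye ratio: green emission scales with cell
size only, red with size times a potential factor, so red/green cancels
size exactly by construction; the ionophore (CCCP) condition collapses
the potential and anchors the low end of the ordering.

## Drift-velocity scaling

In run-tumble population models the chemotactic drift velocity is
proportional to swimming speed, approaching a quadratic dependence for
small attractant gradients. The report maps a relative run-speed change
s to a relative drift change `(1+s)^e − 1` for both exponents e = 1 and
e = 2 and prints both: a 10% speed increase gives +10% (linear) and +21%
(quadratic). The two regimes bracket the commonly quoted 10–20% range;
the quadratic value slightly exceeds the upper end of that rounded
range, and the report deliberately prints both rather than forcing
agreement.

## Synthetic-data generators

**Tethered motor.** Per frame the rotor takes a Poisson-distributed
number of steps with mean `speed · steps_per_rev · dt`, where
`steps_per_rev = bound_units · steps_per_rev_per_unit` (default 50 per
unit) — so recruitment simultaneously raises the speed and smooths the
rotation, as the variance analysis expects. Speed is
`bound_units · unit_increment` (default 4 baseline units × 1.5 Hz).
Recruitment and release are instantaneous unit-count changes at
scheduled times (observed speed changes are step-like; no engagement
kinetics are specified by the data): the 2Dg-like protocol engages one
unit at 300 s after introduction and releases it 200 s later; the
glucose-like protocol engages two units (at 100 s and 650 s) that stay
bound. CW/CCW switching is a two-state Markov process (defaults
0.25 s⁻¹ CCW→CW, 1.25 s⁻¹ CW→CCW, giving bias ≈ 0.83, with a transient
ligand-induced suppression of CCW→CW emulating the chemotactic bias
excursion); CW intervals invert step direction at equal magnitude.
Observation noise is Gaussian on the angle (default 0.05 rad); the two
cell ends sit symmetrically ±1 μm from the tether point.

**Swimming population.** Alternating renewal process at 21 frames/s:
exponential runs (mean 1 s) at fixed heading with speed from the
condition profile; exponential tumbles (mean 0.14 s, ≥ 1 frame) during
which the cell moves at 0.2× run speed and reorients by an angle drawn
from a normal distribution truncated to (0°, 180°] (mean 71°, sd 30°),
applied at a single frame since reorientation is fast compared to the
frame interval. Track durations are uniform over 1–10 s (out-of-plane
loss modeled as truncation) with start times uniform over the session.
Condition profiles are anchored to measured population run speeds:
buffer flat at 20.1 μm/s; glucose-like rising linearly to 29.6 μm/s
over 16.5 min; 2Dg-like rising to 25 μm/s at 6.5 min then returning to
baseline by 16.5 min. Position noise (0.1 μm per coordinate) is added
to all frames.

What the generators do *not* emulate: raw micrographs and segmentation
error structure, cell-to-cell variability in size/tethering geometry,
photobleaching, 3D motion, motor pauses other than the ±0.05 Hz band,
and gradual (non-instantaneous) stator engagement. Passing tests
therefore demonstrate correctness of the analysis chain under the
stated stochastic model, not robustness to every artifact of real
imaging.

### Known small biases

Position noise inflates measured frame speed by approximately σ²/d per
frame (d = true displacement); at default noise this is below 1% net
after segmentation edge effects, but it exceeds 3 SEM once thousands of
runs are pooled. Accuracy tests on population run speeds therefore
allow 3 SEM plus a 0.3 μm/s systematic allowance. Similarly, detected
tumble angles at default noise include noise-inflated maxima; turn-angle
recovery is assessed at reduced position noise.

## Mutant-variant factorization

Strain-like variants are switches on two response channels rather than
molecular models, mirroring what the mutant assays establish: *sensing*
(Trg) produces the transient recruitment; *metabolism* (PTS) produces
sustained recruitment and sets the baseline level (its loss lowers
baseline speed, factor 0.6); *switching* (CheY) controls CW reversals
only. Hence a sensing-null variant shows no 2Dg response but keeps the
glucose (metabolic) response; a metabolism-null variant keeps only the
transient response at a reduced baseline; a switching-null variant runs
smoothly (bias 1) with speed responses intact.

## Experiment driver and problem sizes

`run_experiment` simulates each condition (12 motors × 900 s at 60 fps;
2500 tracks per swimming population; 18 red/green samples), runs all
analyses, compares each condition against the reference with a paired
t-test (per-motor normalized intensity at 10 min) and one-way ANOVA
(red/green ratios), classifies responses (sustained if the normalized
level stays ≥ 1.08 at 10 min; transient if it peaks ≥ 1.08 and returns
below 1.04), and computes drift estimates from the run-speed change.
Comparisons are reported per contrast without multiple-testing
correction (a Bonferroni option exists and is off by default). Reports
are JSON with sorted keys and are byte-identical across runs at a fixed
seed. Tests and the acceptance script use scaled-down sizes (3–12
motors, 120–800 tracks, 100 step-detection replicates, 2000 null
replicates) chosen so the whole suite completes in well under a minute
of simulation time while keeping Monte-Carlo error far from every
asserted margin.

## Numerical choices

- Pause band closed at ±0.05 Hz exactly; samples 1 ulp outside are not
  pauses.
- Unwrapping assumes under half a revolution per frame; traces where a
  frame-to-frame change reaches 0.9π are flagged as inadequately
  sampled rather than rejected.
- Segmentation penalty floor `1e-9·n·mean(y²)` guards against
  float-round-off splits on noiseless traces.
- Empty time bins are reported with n = 0 and NaN mean, not dropped.
- All simulators consume a single integer seed through
  `numpy.random.default_rng`; the experiment driver derives per-stage
  seeds from one root `SeedSequence`.

## Known limitations

- No absolute calibration: stator counts are relative, membrane
  potential is a dimensionless ratio, and the intensity gain is
  arbitrary units.
- Only 2D trajectories; no flow or drift correction.
- CW-interval speeds are classified by sign but not analyzed further.
- The change-point detector assumes piecewise-constant levels; slow
  ramps are reported as their best step approximation or rejected by
  the minimum-step filter.
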