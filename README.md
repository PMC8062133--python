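# motorlab

Quantitative analysis of bacterial flagellar motor output and its
modulation by ligand sensing, for microbiologists and biophysicists
working with tethered-cell rotation assays and swimming-cell tracking.

The *E. coli* motor is powered by stator units (MotA/MotB complexes)
that engage dynamically; at high load each engaged unit adds a discrete
speed increment δ ≈ 1–2 Hz, so the motor speed is f = N·δ for N bound
units. Chemoreceptor signaling is classically thought to set only the
rotational bias, but stator recruitment upon ligand exposure also
changes N itself: transiently for a sensed-only ligand (the
non-metabolizable glucose analog 2-deoxy-D-glucose), persistently for a
metabolized one (glucose). `motorlab` implements the full analysis
chain for detecting and quantifying this:

- **tethered_analysis** — orientation angle θ(t) from cell-end
  coordinates, instantaneous rate f = (dθ/dt)/2π with a ±0.05 Hz pause
  band, 10-sample smoothing, CCW bias, change-point detection of
  discrete speed steps, and stator-number inference from
  revolution-time statistics: for a Poisson stepper with m steps per
  revolution, Var(T)/E(T)² = 1/m, so m̂ = mean²/var per revolution —
  smoother rotation means more engaged units.
- **swim_analysis** — run/tumble segmentation of 2D trajectories
  (tumble: frame speed < half the track mean AND turn angle > 4° at
  21 fps), per-run speeds, binned population statistics, turn angles.
- **intensity_potential** — background-corrected, pre-stimulus-
  normalized GFP-MotB spot intensity; intensity–speed regression;
  membrane-potential red/green dye ratios (R/G cancels cell size).
- **orchestration** — end-to-end simulated experiments across
  conditions and mutant-like variants, paired-t/ANOVA comparisons, and
  the drift-velocity implication: chemotactic drift scales between
  linearly and quadratically with swim speed, so a speed change s maps
  to a drift change (1+s)^e − 1, e ∈ {1, 2}.
- **synthetic_data** — generators for both assays with ground truth:
  Poisson-stepper motor with scheduled stator recruitment, CCW/CW
  switching, run-and-tumble populations with condition-dependent speed
  profiles, and fluorescence models.

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

Simulate a tethered cell exposed to a 2Dg-like protocol (one stator
unit engaging 300 s after introduction, releasing 200 s later) and
analyze the trace:

```sh
motorlab simulate-tethered --out track.csv --protocol 2Dg --duration 700 --seed 42
motorlab analyze-tethered --input track.csv --fps 60 --min-segment 60
```

```json
{
  "ccw_bias": 1.0,
  "mean_ccw_speed_hz": 6.4250268396439605,
  "steps": [
    {
      "delta": 1.497043121261159,
      "post_level": 7.4960279294442,
      "pre_level": 5.998984808183041,
      "t": 299.9166666666667
    },
    {
      "delta": -1.5038496126886463,
      "post_level": 5.992178316755553,
      "pre_level": 7.4960279294442,
      "t": 500.0333333333333
    }
  ]
}
```

The detector recovers the transient recruitment: a +1.5 Hz step within
one frame of t = 300 s (one unit × 1.5 Hz on a 6 Hz, four-unit
baseline) and the matching −1.5 Hz release at t = 500 s; the bias is
1.0 because switching is off by default (a smooth-swimming,
CheY-null-like motor). The same library functions accept measured
cell-end coordinate tables in the same CSV layout.

A full multi-condition experiment (buffer / glucose / 2Dg, with
tethered, swimming, intensity and R/G stages plus statistics) runs
with:

```sh
motorlab run-experiment --seed 1 --out results_dir/
```

and writes `report.json` (byte-identical for a fixed seed) classifying
the glucose response as sustained and the 2Dg response as transient.

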