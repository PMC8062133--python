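"""Synthetic assay generators with known ground truth.

Emulates the two experimental readouts of stator recruitment in E. coli:

* **Tethered-cell assay** — a single motor spins the cell body at high
  load. Motor speed is additive in the number of bound stator units
  (1-2 Hz per unit); the rotor advances as a Poisson stepper (discrete
  angular steps at exponential waiting times, more steps per revolution
  when more units are bound), optionally switching CCW/CW with
  first-order kinetics. Ligand protocols schedule unit recruitment:
  transient for a sensed-only ligand (2-deoxy-D-glucose: ~300 s onset
  delay, ~200 s dwell, return to baseline) or sustained for a sensed and
  metabolized ligand (glucose).

* **Swimming population** — run-and-tumble trajectories at 21 frames/s:
  exponential run durations at a condition-dependent run speed,
  tumbles that slow the cell below half its mean speed and reorient it
  by an angle drawn from a truncated-normal turn-angle distribution
  (population mean 71 degrees for wild type).

* **Fluorescence** — motor-spot intensity proportional to bound units
  over a noisy background (several background-only sites per timepoint),
  and red/green carbocyanine-dye pairs where only the red channel
  carries the membrane-potential factor.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .intensity_potential import RGMeasurement, SpotSeries
from .swim_analysis import Track, TumbleEvent
from .tethered_analysis import EndpointTrack

__all__ = [
    "LigandProtocol",
    "MotorSimParams",
    "MotorSimState",
    "SwimSimParams",
    "IntensitySimParams",
    "mb_protocol",
    "glucose_protocol",
    "twodg_protocol",
    "bound_units_at",
    "simulate_tethered",
    "simulate_swim_population",
    "simulate_spot_series",
    "simulate_rg",
    "constant_profile",
    "linear_rise_profile",
    "rise_and_return_profile",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {msg}")


@dataclass(frozen=True)
class LigandProtocol:
    """Ligand exposure schedule and its effect on the motor.

    ``recruited_units`` stator units engage one by one starting
    ``onset_delay`` seconds after introduction at ``t_intro``, spaced by
    ``recruit_stagger``; each disengages ``dwell`` seconds after its own
    engagement (``dwell=None`` means sustained engagement, as when
    metabolism keeps the proton motive force elevated).
    ``bias_excursion`` is the transient fractional suppression of the
    CCW->CW switching rate right after introduction (the classic
    chemotactic bias response), relaxing with ``bias_recovery_time``.
    """

    label: str
    concentration_uM: float = 1000.0
    t_intro: float = 0.0
    onset_delay: float = 0.0
    recruited_units: int = 0
    dwell: float | None = None
    recruit_stagger: float = 0.0
    bias_excursion: float = 0.0
    bias_recovery_time: float = 60.0

    def __post_init__(self):
        _require(self.onset_delay >= 0, "onset_delay", "must be >= 0")
        _require(self.recruited_units >= 0, "recruited_units", "must be >= 0")
        _require(self.dwell is None or self.dwell > 0, "dwell", "must be positive or None")
        _require(0.0 <= self.bias_excursion <= 1.0, "bias_excursion", "must be in [0, 1]")
        _require(self.bias_recovery_time > 0, "bias_recovery_time", "must be positive")
        _require(self.recruit_stagger >= 0, "recruit_stagger", "must be >= 0")

    def recruitment_events(self) -> list[tuple[float, float | None]]:
        """(engage time, disengage time or None) per recruited unit."""
        events = []
        for j in range(self.recruited_units):
            t_on = self.t_intro + self.onset_delay + j * self.recruit_stagger
            t_off = None if self.dwell is None else t_on + self.dwell
            events.append((t_on, t_off))
        return events


def mb_protocol() -> LigandProtocol:
    """Plain motility buffer: no ligand, no recruitment."""
    return LigandProtocol(label="MB", concentration_uM=0.0, recruited_units=0)


def glucose_protocol(t_intro: float = 0.0) -> LigandProtocol:
    """Sensed and metabolized ligand: sustained recruitment.

    Two units engage (first ~100 s, second ~650 s after introduction,
    matching observed step times) and stay bound.
    """
    return LigandProtocol(
        label="glucose", t_intro=t_intro, onset_delay=100.0,
        recruited_units=2, dwell=None, recruit_stagger=550.0,
        bias_excursion=0.5,
    )


def twodg_protocol(t_intro: float = 0.0) -> LigandProtocol:
    """Sensed-only ligand (2-deoxy-D-glucose): transient recruitment.

    One unit engages ~300 s after introduction and disengages ~200 s
    later, returning the motor to its pre-stimulus speed.
    """
    return LigandProtocol(
        label="2Dg", t_intro=t_intro, onset_delay=300.0,
        recruited_units=1, dwell=200.0, bias_excursion=0.3,
    )


@dataclass(frozen=True)
class MotorSimParams:
    """Tethered-motor simulation parameters.

    ``unit_increment`` is the speed added per bound stator unit at high
    load (observed engagement steps are 1.0-2.0 Hz).
    ``steps_per_rev_per_unit`` sets the Poisson-stepper resolution: a
    motor with u bound units takes u * steps_per_rev_per_unit steps per
    revolution, so more units give smoother rotation (smaller
    revolution-time variance).
    """

    duration: float
    fps: float = 60.0
    baseline_units: int = 4
    unit_increment: float = 1.5
    steps_per_rev_per_unit: int = 50
    ccw_to_cw_rate: float = 0.0
    cw_to_ccw_rate: float = 0.0
    angle_noise_sd: float = 0.05
    cell_half_length: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("duration", "fps", "unit_increment", "cell_half_length"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, name, "must be positive and finite")
        _require(self.baseline_units >= 1, "baseline_units", "must be >= 1")
        _require(self.steps_per_rev_per_unit >= 1, "steps_per_rev_per_unit", "must be >= 1")
        _require(self.ccw_to_cw_rate >= 0, "ccw_to_cw_rate", "must be >= 0")
        _require(self.cw_to_ccw_rate >= 0, "cw_to_ccw_rate", "must be >= 0")
        _require(self.angle_noise_sd >= 0, "angle_noise_sd", "must be >= 0")
        _require(self.duration * self.fps >= 2, "duration", "needs at least 2 frames")


@dataclass(frozen=True)
class MotorSimState:
    """Ground-truth per-frame state of the simulated motor.

    ``true_speed`` = bound_units * unit_increment, signed (+ CCW, - CW);
    ``true_angle`` is the unwrapped rotor angle before observation noise.
    """

    t: np.ndarray
    true_angle: np.ndarray
    bound_units: np.ndarray
    ccw: np.ndarray
    true_speed: np.ndarray
    fps: float

    def units_at(self, times) -> np.ndarray:
        """Bound-unit count at arbitrary times (nearest frame)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.clip(np.round(times * self.fps).astype(int), 0, len(self.t) - 1)
        return self.bound_units[idx]


def bound_units_at(params: MotorSimParams, protocol: LigandProtocol, t: np.ndarray) -> np.ndarray:
    """Ground-truth bound stator units at frame times ``t``."""
    units = np.full(len(t), params.baseline_units, dtype=int)
    for t_on, t_off in protocol.recruitment_events():
        active = t >= t_on if t_off is None else (t >= t_on) & (t < t_off)
        units[active] += 1
    return units


def simulate_tethered(
    params: MotorSimParams, protocol: LigandProtocol
) -> tuple[EndpointTrack, MotorSimState]:
    """Simulate one tethered rotating cell under a ligand protocol.

    Per frame, the rotor takes a Poisson-distributed number of discrete
    steps (mean = speed * steps_per_rev * dt), each advancing
    2*pi/steps_per_rev in the current switch-state direction; Gaussian
    angular observation noise is added before the angle is converted to
    the coordinates of the two cell ends, placed symmetrically
    ``cell_half_length`` from the tether point.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fps))
    dt = 1.0 / params.fps
    t = np.arange(n) * dt
    units = bound_units_at(params, protocol, t)
    speed_mag = units * params.unit_increment

    # CCW/CW two-state switching; ligand transiently suppresses CCW->CW
    ccw = np.ones(n, dtype=bool)
    if params.ccw_to_cw_rate > 0 or params.cw_to_ccw_rate > 0:
        supp = np.ones(n)
        if protocol.bias_excursion > 0:
            after = t >= protocol.t_intro
            supp[after] = 1.0 - protocol.bias_excursion * np.exp(
                -(t[after] - protocol.t_intro) / protocol.bias_recovery_time
            )
        u = rng.random(n)
        state = True  # start CCW (the motor's null state)
        for i in range(n):
            ccw[i] = state
            if state:
                p = 1.0 - math.exp(-params.ccw_to_cw_rate * supp[i] * dt)
            else:
                p = 1.0 - math.exp(-params.cw_to_ccw_rate * dt)
            if u[i] < p:
                state = not state

    steps_per_rev = units * params.steps_per_rev_per_unit
    mean_steps = speed_mag * steps_per_rev * dt
    n_steps = rng.poisson(mean_steps)
    dtheta = np.where(ccw, 1.0, -1.0) * n_steps * (2.0 * np.pi / steps_per_rev)
    true_angle = np.concatenate(([0.0], np.cumsum(dtheta)))[:n]
    obs_angle = true_angle + rng.normal(0.0, params.angle_noise_sd, n) \
        if params.angle_noise_sd > 0 else true_angle

    u_vec = np.column_stack((np.cos(obs_angle), np.sin(obs_angle)))
    end1 = -params.cell_half_length * u_vec
    end2 = params.cell_half_length * u_vec
    track = EndpointTrack(t=t, end1=end1, end2=end2, fps=params.fps)
    state = MotorSimState(
        t=t, true_angle=true_angle, bound_units=units, ccw=ccw,
        true_speed=np.where(ccw, speed_mag, -speed_mag), fps=params.fps,
    )
    return track, state


# ---------------------------------------------------------------------------
# Swimming populations


def constant_profile(v: float) -> Callable[[float], float]:
    """Stationary run-speed profile (motility buffer)."""
    return lambda t: v


def linear_rise_profile(
    v0: float, v1: float, t_end: float
) -> Callable[[float], float]:
    """Monotone rise from v0 to v1 over [0, t_end], then flat (sustained
    response to a metabolized ligand)."""

    def profile(t: float) -> float:
        x = min(max(t, 0.0), t_end) / t_end
        return v0 + (v1 - v0) * x

    return profile


def rise_and_return_profile(
    v0: float, v_peak: float, t_peak: float, t_return: float
) -> Callable[[float], float]:
    """Rise to v_peak at t_peak then return to v0 by t_return (transient
    response to a sensed-only ligand)."""

    def profile(t: float) -> float:
        if t <= 0:
            return v0
        if t <= t_peak:
            return v0 + (v_peak - v0) * t / t_peak
        if t <= t_return:
            return v_peak + (v0 - v_peak) * (t - t_peak) / (t_return - t_peak)
        return v0

    return profile


def speed_profile_for(protocol: LigandProtocol, v0: float = 20.1) -> Callable[[float], float]:
    """Default condition profiles, anchored to measured population run
    speeds: buffer flat ~20 um/s; glucose rising ~50% by 16.5 min; 2Dg
    peaking ~25 um/s near 6.5 min then returning to baseline."""
    if protocol.label == "glucose":
        return linear_rise_profile(v0, 29.6, 990.0)
    if protocol.label == "2Dg":
        return rise_and_return_profile(v0, 25.0, 390.0, 990.0)
    return constant_profile(v0)


@dataclass(frozen=True)
class SwimSimParams:
    """Run-and-tumble population simulation parameters.

    ``speed_profile`` maps absolute time (s) to mean run speed (um/s);
    when None it is derived from the ligand protocol. Track start times
    are uniform over ``session_duration`` and track lengths uniform over
    ``track_duration_range`` (out-of-plane loss appears as truncation).
    """

    n_tracks: int
    fps: float = 21.0
    speed_profile: Callable[[float], float] | None = None
    run_duration_mean: float = 1.0
    tumble_duration_mean: float = 0.14
    turn_angle_mean: float = 71.0
    turn_angle_sd: float = 30.0
    tumble_speed_factor: float = 0.2
    position_noise_sd: float = 0.1
    track_duration_range: tuple[float, float] = (1.0, 10.0)
    session_duration: float = 990.0
    seed: int = 0

    def __post_init__(self):
        _require(self.n_tracks >= 1, "n_tracks", "must be >= 1")
        _require(self.fps > 0, "fps", "must be positive")
        _require(self.run_duration_mean > 0, "run_duration_mean", "must be positive")
        _require(self.tumble_duration_mean >= 0, "tumble_duration_mean", "must be >= 0")
        _require(0 < self.turn_angle_mean < 180, "turn_angle_mean", "must be in (0, 180)")
        _require(self.turn_angle_sd > 0, "turn_angle_sd", "must be positive")
        _require(0 <= self.tumble_speed_factor < 0.5, "tumble_speed_factor",
                 "must be in [0, 0.5) so tumbles satisfy the speed criterion")
        _require(self.position_noise_sd >= 0, "position_noise_sd", "must be >= 0")
        lo, hi = self.track_duration_range
        _require(0 < lo <= hi, "track_duration_range", "must be positive and ordered")


def _draw_turn_angle(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Turn-angle magnitude in degrees from a normal truncated to (0, 180]."""
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if 0.0 < a <= 180.0:
            return a
    return mean  # pragma: no cover - practically unreachable


def simulate_swim_population(
    params: SwimSimParams, protocol: LigandProtocol | None = None
) -> tuple[list[Track], dict[int, list[TumbleEvent]]]:
    """Simulate a population of run-and-tumble trajectories.

    Each track is an alternating renewal process: exponential runs at
    fixed heading and speed from the condition profile, then tumbles of
    exponential duration during which the cell moves at
    ``tumble_speed_factor`` of its run speed and reorients by a drawn
    turn angle (applied at a single frame, as reorientation is fast
    compared to the frame interval). Gaussian observation noise is added
    to positions. Ground-truth tumble events are returned per track.
    """
    profile = params.speed_profile
    if profile is None:
        profile = speed_profile_for(protocol if protocol is not None else mb_protocol())
    if profile(0.0) < 0 or profile(params.session_duration) < 0:
        raise ValueError("invalid speed_profile: negative speeds")
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.fps
    tracks: list[Track] = []
    truth: dict[int, list[TumbleEvent]] = {}
    for tid in range(params.n_tracks):
        lo, hi = params.track_duration_range
        duration = rng.uniform(lo, hi)
        t0 = rng.uniform(0.0, max(params.session_duration - duration, 0.0))
        n = max(int(round(duration * params.fps)), 2)
        t = t0 + np.arange(n) * dt

        # schedule run/tumble intervals over the track
        tumbling = np.zeros(n, dtype=bool)
        reorient_frame: dict[int, float] = {}
        events: list[TumbleEvent] = []
        tau = 0.0
        last_frame = -1
        while tau < duration:
            run_len = rng.exponential(params.run_duration_mean)
            tau += run_len
            if tau >= duration or params.tumble_duration_mean == 0:
                break
            tum_len = max(rng.exponential(params.tumble_duration_mean), dt)
            i0 = max(int(tau / dt), last_frame + 1)  # rasterized events stay disjoint
            i1 = min(int((tau + tum_len) / dt), n - 1)
            if i0 >= n - 1 or i0 > i1:
                break
            last_frame = i1 + 1
            tumbling[i0 : i1 + 1] = True
            angle = _draw_turn_angle(rng, params.turn_angle_mean, params.turn_angle_sd)
            reorient_frame[(i0 + i1) // 2] = angle * (1 if rng.random() < 0.5 else -1)
            events.append(
                TumbleEvent(t_start=float(t[i0]), t_end=float(t[min(i1 + 1, n - 1)]),
                            max_turn_angle=angle)
            )
            tau += tum_len

        heading = rng.uniform(0.0, 2.0 * np.pi)
        xy = np.zeros((n, 2))
        speed_fraction = 1.0  # exact profile speed during runs
        for i in range(1, n):
            j = i - 1  # displacement from frame j to i
            if j in reorient_frame:
                heading += math.radians(reorient_frame[j])
            v = profile(t[j])
            frac = params.tumble_speed_factor if tumbling[j] else speed_fraction
            step = v * frac * dt
            xy[i] = xy[j] + (step * math.cos(heading), step * math.sin(heading))
        if params.position_noise_sd > 0:
            xy = xy + rng.normal(0.0, params.position_noise_sd, xy.shape)
        tracks.append(Track(track_id=tid, t=t, xy=xy, fps=params.fps))
        truth[tid] = events
    return tracks, truth


# ---------------------------------------------------------------------------
# Fluorescence


@dataclass(frozen=True)
class IntensitySimParams:
    """Motor-spot fluorescence simulation: intensity = gain * bound
    units + background, with Gaussian noise, plus ``n_background_sites``
    background-only readings per timepoint."""

    gain: float
    background_mean: float
    noise_sd: float
    timepoints: tuple[float, ...]
    n_background_sites: int = 3
    seed: int = 0

    def __post_init__(self):
        _require(self.gain > 0, "gain", "must be positive")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.n_background_sites >= 1, "n_background_sites", "must be >= 1")
        _require(len(self.timepoints) >= 1, "timepoints", "must not be empty")


def simulate_spot_series(params: IntensitySimParams, truth: MotorSimState) -> SpotSeries:
    """Sample spot and background fluorescence at the given timepoints of
    a simulated motor's ground-truth bound-unit timeline."""
    tp = np.asarray(params.timepoints, dtype=float)
    t_max = truth.t[-1] + 1.0 / truth.fps
    if np.any(tp < truth.t[0]) or np.any(tp > t_max):
        raise ValueError("timepoint outside the simulated duration")
    rng = np.random.default_rng(params.seed)
    units = truth.units_at(tp)
    noise = lambda size: rng.normal(0.0, params.noise_sd, size) if params.noise_sd > 0 else 0.0
    raw = params.gain * units + params.background_mean + noise(len(tp))
    bg = params.background_mean + np.zeros((len(tp), params.n_background_sites)) + noise(
        (len(tp), params.n_background_sites)
    )
    return SpotSeries(t=tp, raw_spot=raw, background_reads=bg)


def simulate_rg(
    potential_factor: float,
    size_factor: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RGMeasurement:
    """One red/green dye measurement: green = size * (1 + eps),
    red = size * potential * (1 + eps'); only red carries the
    membrane-potential factor, so red/green cancels cell size."""
    if not (potential_factor > 0 and size_factor > 0):
        raise ValueError("potential_factor and size_factor must be positive")
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        e1, e2 = rng.normal(0.0, noise_sd, 2)
        e1, e2 = max(e1, -0.9), max(e2, -0.9)
    else:
        e1 = e2 = 0.0
    green = size_factor * (1.0 + e1)
    red = size_factor * potential_factor * (1.0 + e2)
    return RGMeasurement(red=red, green=green)
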