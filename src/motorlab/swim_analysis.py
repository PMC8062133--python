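"""Run-and-tumble segmentation of swimming trajectories.

Swimming E. coli alternate straight runs (all flagella CCW, bundled) with
brief tumbles (one or more flagella CW) that reorient the cell. From 2D
trajectories sampled at fixed frame rate this module computes per-frame
kinematics, detects tumbles with the joint speed/turn-angle criterion
(speed below half the track mean AND inter-frame turn angle above 4
degrees), partitions tracks into runs, and aggregates population
run-speed statistics over time bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tethered_analysis import UndefinedStatisticError

__all__ = [
    "Track",
    "TrackKinematics",
    "TumbleEvent",
    "RunSegment",
    "PopulationSpeedStats",
    "compute_kinematics",
    "filter_tracks",
    "detect_tumbles",
    "segment_runs",
    "segment_track",
    "population_run_speed",
    "mean_turn_angle",
    "tumble_detection_score",
    "MIN_TRACK_DURATION_S",
    "TUMBLE_SPEED_FACTOR",
    "TUMBLE_ANGLE_THRESHOLD_DEG",
]

#: Tracks must last longer than this (seconds) to exclude out-of-plane blips.
MIN_TRACK_DURATION_S = 0.5
#: Tumble frame requires speed < factor * track mean speed ...
TUMBLE_SPEED_FACTOR = 0.5
#: ... AND turn angle above this (degrees) between successive frames.
TUMBLE_ANGLE_THRESHOLD_DEG = 4.0


@dataclass(frozen=True)
class Track:
    """One cell trajectory, uniformly sampled.

    ``t`` are absolute times in seconds (track start may be anywhere in
    the experiment), ``xy`` positions in micrometres.
    """

    track_id: int
    t: np.ndarray
    xy: np.ndarray
    fps: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        if len(t) < 2 or xy.shape != (len(t), 2):
            raise ValueError("Track needs >= 2 frames of (x, y) positions")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class TrackKinematics:
    """Per-frame kinematics of one track.

    ``frame_speed[i]`` is the speed over the displacement from frame i to
    i+1 (length n-1). ``turn_angle[i]`` is the angle in degrees between
    the displacements (i-1 -> i) and (i -> i+1), stored for interior
    frames i = 1..n-2 (length n-2). Frames with zero displacement have an
    undefined direction; their turn angle is recorded as 0 and flagged.
    """

    track_id: int
    t: np.ndarray
    fps: float
    frame_speed: np.ndarray
    turn_angle: np.ndarray
    turn_undefined: np.ndarray
    mean_speed: float


@dataclass(frozen=True)
class TumbleEvent:
    """A maximal block of consecutive tumble frames."""

    t_start: float
    t_end: float
    max_turn_angle: float


@dataclass(frozen=True)
class RunSegment:
    """A maximal tumble-free interval; ``run_speed`` is the mean frame
    speed inside it."""

    t_start: float
    t_end: float
    run_speed: float
    n_frames: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class PopulationSpeedStats:
    """Run-speed statistics of all runs whose midpoint falls in a time bin."""

    bin_start: float
    bin_end: float
    mean_run_speed: float
    sem: float
    n_runs: int
    n_cells: int


def compute_kinematics(track: Track) -> TrackKinematics:
    """Frame speeds, turn angles and mean speed of one track."""
    disp = np.diff(track.xy, axis=0)
    step = np.hypot(disp[:, 0], disp[:, 1])
    frame_speed = step * track.fps
    # angle between successive displacement vectors at interior frames
    a, b = disp[:-1], disp[1:]
    dot = np.einsum("ij,ij->i", a, b)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    undef = (step[:-1] == 0) | (step[1:] == 0)
    ang = np.where(undef, 0.0, ang)
    return TrackKinematics(
        track_id=track.track_id,
        t=track.t,
        fps=track.fps,
        frame_speed=frame_speed,
        turn_angle=ang,
        turn_undefined=undef,
        mean_speed=float(np.mean(frame_speed)),
    )


def filter_tracks(tracks: list[Track], min_duration: float = MIN_TRACK_DURATION_S) -> list[Track]:
    """Keep tracks strictly longer than ``min_duration`` seconds
    (short tracks are dominated by cells crossing the focal plane)."""
    return [tr for tr in tracks if tr.duration > min_duration]


def detect_tumbles(
    kin: TrackKinematics,
    speed_factor: float = TUMBLE_SPEED_FACTOR,
    angle_threshold: float = TUMBLE_ANGLE_THRESHOLD_DEG,
    merge_gap: int = 1,
) -> list[TumbleEvent]:
    """Tumble events of one track.

    An interior frame i is a tumble frame iff
    ``frame_speed[i] < speed_factor * mean_speed`` and
    ``turn_angle[i] > angle_threshold``; consecutive tumble frames merge
    into a single event spanning [t[i_first], t[i_last + 1]]. Blocks
    separated by at most ``merge_gap`` non-qualifying frames are joined
    (a single sub-threshold frame inside a reorientation does not split
    the event).
    """
    n_int = len(kin.turn_angle)
    if n_int == 0:
        return []
    speed_i = kin.frame_speed[1 : n_int + 1]  # speed leaving interior frame i
    is_tumble = (speed_i < speed_factor * kin.mean_speed) & (
        kin.turn_angle > angle_threshold
    )
    events: list[TumbleEvent] = []
    idx = np.flatnonzero(is_tumble)
    if idx.size == 0:
        return events
    # split into blocks, closing gaps of up to merge_gap frames
    blocks = np.split(idx, np.flatnonzero(np.diff(idx) > 1 + merge_gap) + 1)
    for blk in blocks:
        first, last = int(blk[0]) + 1, int(blk[-1]) + 1  # interior -> frame index
        events.append(
            TumbleEvent(
                t_start=float(kin.t[first]),
                t_end=float(kin.t[min(last + 1, len(kin.t) - 1)]),
                max_turn_angle=float(np.max(kin.turn_angle[blk])),
            )
        )
    return events


def segment_runs(
    kin: TrackKinematics,
    tumbles: list[TumbleEvent],
    min_run_frames: int = 3,
) -> list[RunSegment]:
    """Maximal intervals between consecutive tumbles (and track ends).

    Runs shorter than ``min_run_frames`` frames are discarded; tumbles at
    the track boundary produce no flanking zero-length run.
    """
    dt = 1.0 / kin.fps
    edges = [float(kin.t[0])]
    for ev in sorted(tumbles, key=lambda e: e.t_start):
        edges.extend([ev.t_start, ev.t_end])
    edges.append(float(kin.t[-1]))
    runs: list[RunSegment] = []
    t_speed = kin.t[:-1]  # frame_speed[i] covers [t[i], t[i+1])
    for a, b in zip(edges[::2], edges[1::2]):
        sel = (t_speed >= a - 0.5 * dt) & (t_speed < b - 0.5 * dt)
        n = int(np.sum(sel))
        if n < min_run_frames or b <= a:
            continue
        runs.append(
            RunSegment(
                t_start=a, t_end=b,
                run_speed=float(np.mean(kin.frame_speed[sel])),
                n_frames=n,
            )
        )
    return runs


def segment_track(
    track: Track,
    speed_factor: float = TUMBLE_SPEED_FACTOR,
    angle_threshold: float = TUMBLE_ANGLE_THRESHOLD_DEG,
    min_run_frames: int = 3,
) -> tuple[list[RunSegment], list[TumbleEvent]]:
    """Convenience wrapper: kinematics -> tumbles -> runs for one track."""
    kin = compute_kinematics(track)
    tumbles = detect_tumbles(kin, speed_factor, angle_threshold)
    return segment_runs(kin, tumbles, min_run_frames), tumbles


def population_run_speed(
    tracks: list[Track],
    bin_edges: np.ndarray,
    speed_factor: float = TUMBLE_SPEED_FACTOR,
    angle_threshold: float = TUMBLE_ANGLE_THRESHOLD_DEG,
    min_run_frames: int = 3,
) -> list[PopulationSpeedStats]:
    """Mean run speed per time bin across a track population.

    A run contributes to the bin containing its midpoint. Empty bins are
    reported with ``n_runs = 0`` and NaN mean. Both the number of runs
    and the number of distinct cells (tracks) per bin are reported.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for tr in tracks:
        runs, _ = segment_track(tr, speed_factor, angle_threshold, min_run_frames)
        for run in runs:
            rows.append((tr.track_id, run.midpoint, run.run_speed))
    df = pd.DataFrame(rows, columns=["track_id", "midpoint", "run_speed"])
    out = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sub = df[(df.midpoint >= lo) & (df.midpoint < hi)]
        n = len(sub)
        if n == 0:
            out.append(PopulationSpeedStats(lo, hi, float("nan"), float("nan"), 0, 0))
            continue
        sem = float(sub.run_speed.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            PopulationSpeedStats(
                bin_start=float(lo), bin_end=float(hi),
                mean_run_speed=float(sub.run_speed.mean()),
                sem=sem, n_runs=n, n_cells=int(sub.track_id.nunique()),
            )
        )
    return out


def mean_turn_angle(
    tracks: list[Track],
    speed_factor: float = TUMBLE_SPEED_FACTOR,
    angle_threshold: float = TUMBLE_ANGLE_THRESHOLD_DEG,
) -> float:
    """Mean of the per-tumble maximum turn angle over all detected
    tumbles in the population, in degrees."""
    angles = []
    for tr in tracks:
        _, tumbles = segment_track(tr, speed_factor, angle_threshold)
        angles.extend(ev.max_turn_angle for ev in tumbles)
    if not angles:
        raise UndefinedStatisticError("no tumbles detected: mean turn angle undefined")
    return float(np.mean(angles))


def tumble_detection_score(
    detected: list[TumbleEvent],
    truth: list[TumbleEvent],
    tol: float = 0.25,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs ground-truth tumbles.

    Two events match when their intervals, dilated by ``tol`` seconds,
    overlap. Returns (true positives, false positives, false negatives).
    """
    used = [False] * len(truth)
    tp = 0
    for d in detected:
        for j, g in enumerate(truth):
            if used[j]:
                continue
            if d.t_start - tol <= g.t_end and g.t_start - tol <= d.t_end:
                used[j] = True
                tp += 1
                break
    return tp, len(detected) - tp, len(truth) - tp
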