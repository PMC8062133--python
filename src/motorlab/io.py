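"""Readers and writers for the delimited-text table formats.

All on-disk formats are plain CSV/JSON/YAML:

* endpoint tracks: ``frame,t_s,x1_um,y1_um,x2_um,y2_um``
* swim tracks:     ``track_id,frame,t_s,x_um,y_um``
* spot series:     ``t_s,raw_spot,bg1,...,bgN``
* red/green:       ``condition,red,green``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intensity_potential import RGMeasurement, SpotSeries
from .swim_analysis import Track, TumbleEvent
from .tethered_analysis import EndpointTrack

__all__ = [
    "write_endpoint_track", "read_endpoint_track",
    "write_tracks", "read_tracks",
    "write_spot_series", "read_spot_series",
    "write_rg", "read_rg",
    "write_truth_json", "read_truth_json",
    "write_config", "read_config",
]


def _infer_fps(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def write_endpoint_track(track: EndpointTrack, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(track)),
            "t_s": track.t,
            "x1_um": track.end1[:, 0],
            "y1_um": track.end1[:, 1],
            "x2_um": track.end2[:, 0],
            "y2_um": track.end2[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_endpoint_track(path, fps: float | None = None) -> EndpointTrack:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    return EndpointTrack(
        t=t,
        end1=df[["x1_um", "y1_um"]].to_numpy(float),
        end2=df[["x2_um", "y2_um"]].to_numpy(float),
        fps=fps if fps is not None else _infer_fps(t),
    )


def write_tracks(tracks: list[Track], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": np.arange(len(tr)),
                    "t_s": tr.t,
                    "x_um": tr.xy[:, 0],
                    "y_um": tr.xy[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path, fps: float | None = None) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        t = sub["t_s"].to_numpy(float)
        tracks.append(
            Track(
                track_id=int(tid),
                t=t,
                xy=sub[["x_um", "y_um"]].to_numpy(float),
                fps=fps if fps is not None else _infer_fps(t),
            )
        )
    return tracks


def write_spot_series(series: SpotSeries, path) -> None:
    n_bg = series.background_reads.shape[1]
    data = {"t_s": series.t, "raw_spot": series.raw_spot}
    for j in range(n_bg):
        data[f"bg{j + 1}"] = series.background_reads[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_spot_series(path) -> SpotSeries:
    df = pd.read_csv(path)
    bg_cols = [c for c in df.columns if c.startswith("bg")]
    if not bg_cols:
        raise ValueError("spot series CSV needs at least one bg column")
    return SpotSeries(
        t=df["t_s"].to_numpy(float),
        raw_spot=df["raw_spot"].to_numpy(float),
        background_reads=df[bg_cols].to_numpy(float),
    )


def write_rg(measurements: dict[str, list[RGMeasurement]], path) -> None:
    rows = [
        {"condition": cond, "red": m.red, "green": m.green}
        for cond, ms in measurements.items()
        for m in ms
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rg(path) -> dict[str, list[RGMeasurement]]:
    df = pd.read_csv(path)
    out: dict[str, list[RGMeasurement]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["condition"]), []).append(
            RGMeasurement(red=float(row["red"]), green=float(row["green"]))
        )
    return out


def write_truth_json(truth, path) -> None:
    """Serialize simulator ground truth (motor state or per-track tumble
    events) to JSON."""
    if hasattr(truth, "bound_units"):  # MotorSimState
        payload = {
            "kind": "motor_state",
            "fps": truth.fps,
            "t": truth.t.tolist(),
            "true_angle": truth.true_angle.tolist(),
            "bound_units": truth.bound_units.tolist(),
            "ccw": truth.ccw.astype(int).tolist(),
            "true_speed": truth.true_speed.tolist(),
        }
    else:  # dict of track_id -> [TumbleEvent]
        payload = {
            "kind": "tumble_events",
            "tracks": {
                str(tid): [
                    {"t_start": e.t_start, "t_end": e.t_end,
                     "max_turn_angle": e.max_turn_angle}
                    for e in events
                ]
                for tid, events in truth.items()
            },
        }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_truth_json(path):
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "tumble_events":
        return {
            int(tid): [TumbleEvent(**e) for e in events]
            for tid, events in payload["tracks"].items()
        }
    return payload


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
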