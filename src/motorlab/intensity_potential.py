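"""Fluorescence quantification: stator-spot intensity and membrane potential.

GFP-tagged stator units (GFP-MotB) form a diffraction-limited spot at the
motor whose intensity is proportional to the number of bound units. Raw
spot values are corrected by subtracting the mean of several background
readings taken around the cell, then normalized to the pre-stimulus mean
so recruitment appears as a relative rise. Intensity is regressed against
motor speed to test the linear stator-speed relation.

Membrane potential is proxied by the carbocyanine dye ratio: green
emission scales with cell size only, red with size times a
potential-dependent factor, so the red/green ratio cancels size and
tracks potential (lowest under the ionophore CCCP, which collapses it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "SpotSeries",
    "RGMeasurement",
    "RegressionResult",
    "background_correct",
    "normalize_series",
    "intensity_speed_regression",
    "rg_ratio",
]


@dataclass(frozen=True)
class SpotSeries:
    """Time-stamped motor-spot fluorescence with background readings.

    ``background_reads`` has shape (n_timepoints, n_sites); ``corrected``
    is raw minus the per-timepoint background mean; ``normalized`` (set
    by :func:`normalize_series`) is corrected divided by the pre-stimulus
    mean. ``negative_corrected`` flags timepoints where correction went
    below zero (kept, not clipped).
    """

    t: np.ndarray
    raw_spot: np.ndarray
    background_reads: np.ndarray
    corrected: np.ndarray = field(init=False)
    normalized: np.ndarray | None = None
    negative_corrected: np.ndarray = field(init=False)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        raw = np.asarray(self.raw_spot, dtype=float)
        bg = np.atleast_2d(np.asarray(self.background_reads, dtype=float))
        if bg.shape[0] != len(t) or len(raw) != len(t):
            raise ValueError("t, raw_spot and background_reads rows must align")
        if bg.shape[1] < 1:
            raise ValueError("need at least one background read per timepoint")
        corrected = raw - bg.mean(axis=1)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "raw_spot", raw)
        object.__setattr__(self, "background_reads", bg)
        object.__setattr__(self, "corrected", corrected)
        object.__setattr__(self, "negative_corrected", corrected < 0)
        if np.any(corrected < 0):
            warnings.warn("background-corrected intensity below zero at some timepoints")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class RGMeasurement:
    """Paired red (620 nm) and green (520 nm) dye fluorescence of one
    sample; ``ratio`` = red/green is the size-free potential proxy."""

    red: float
    green: float

    def __post_init__(self):
        if not (self.green > 0):
            raise ValueError("green fluorescence must be positive")
        if not np.isfinite(self.red):
            raise ValueError("red fluorescence must be finite")

    @property
    def ratio(self) -> float:
        return self.red / self.green


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def background_correct(raw_spot: float, background_reads) -> float:
    """Raw spot intensity minus the arithmetic mean of the background
    readings. May be negative (flagged upstream, never clipped)."""
    bg = np.asarray(background_reads, dtype=float)
    if bg.size == 0:
        raise ValueError("background_reads must not be empty")
    return float(raw_spot - bg.mean())


def normalize_series(series: SpotSeries, t_intro: float) -> SpotSeries:
    """Normalize corrected intensity to the mean over all points strictly
    before ligand introduction at ``t_intro``."""
    pre = series.corrected[series.t < t_intro]
    if pre.size == 0:
        raise ValueError("no pre-stimulus timepoints before t_intro")
    baseline = float(pre.mean())
    if baseline <= 0:
        raise ValueError("pre-stimulus mean intensity must be positive")
    return replace(series, normalized=series.corrected / baseline)


def intensity_speed_regression(intensities, speeds) -> RegressionResult:
    """OLS fit of (normalized) spot intensity on (normalized) motor speed.

    A slope near the gain ratio with high r^2 supports intensity and
    speed both reporting the same bound-stator count.
    """
    x = np.asarray(speeds, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired (intensity, speed) points")
    if np.ptp(x) == 0:
        raise ValueError("speeds have zero variance: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def rg_ratio(
    measurements: dict[str, list[RGMeasurement]],
) -> tuple[dict[str, float], list[str]]:
    """Per-condition mean red/green ratio and the condition ordering.

    Returns ``(ratios, order)`` where ``order`` lists conditions from
    lowest to highest mean ratio (lowest expected for CCCP-treated
    cells, whose membrane potential is abolished).
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    ratios = {}
    for cond, ms in measurements.items():
        if not ms:
            raise ValueError(f"condition {cond!r} has no measurements")
        ratios[cond] = float(np.mean([m.ratio for m in ms]))
    order = sorted(ratios, key=ratios.get)
    return ratios, order
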