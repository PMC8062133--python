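"""End-to-end experiment driver.

Simulates a set of conditions (buffer, glucose-like, 2Dg-like, across
wild-type-like and mutant-like variants), runs every analysis stage
(tethered rotation, swimming population, spot intensity, red/green
potential), compares conditions against the buffer reference with the
standard tests, computes the chemotactic drift-velocity implication of a
run-speed change, and emits a deterministic JSON report.

Mutant variants are modeled as switches on two response channels, which
is the factorization the mutant assays establish:

* ``sensing`` (Trg receptor): transient stator recruitment on ligand
  sensing; disabling it removes the 2Dg response entirely.
* ``metabolism`` (PTS): sustained recruitment via elevated proton motive
  force when the ligand is metabolized; disabling it leaves only the
  transient sensing response and lowers the baseline.
* ``switching`` (CheY): CCW/CW reversals; disabling it locks the motor
  CCW (smooth-swimming), without touching speed modulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from . import intensity_potential as ip
from . import swim_analysis as swim
from . import synthetic_data as syn
from . import tethered_analysis as teth

__all__ = [
    "StrainProfile",
    "STRAINS",
    "DriftEstimate",
    "ConditionComparison",
    "ExperimentConfig",
    "drift_velocity_change",
    "compare_conditions",
    "condition_protocol",
    "swim_profile_for",
    "potential_factor_for",
    "run_experiment",
]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class StrainProfile:
    """Response channels of a strain-like variant."""

    label: str
    sensing: bool = True
    metabolism: bool = True
    switching: bool = True
    baseline_factor: float = 1.0


STRAINS = {
    "WT": StrainProfile("WT"),
    "delta-cheY": StrainProfile("delta-cheY", switching=False),
    "delta-trg": StrainProfile("delta-trg", sensing=False),
    "delta-ptsI": StrainProfile("delta-ptsI", metabolism=False, baseline_factor=0.6),
}


@dataclass(frozen=True)
class DriftEstimate:
    """Chemotactic drift-velocity change implied by a run-speed change.

    In run-tumble population models the drift velocity is proportional
    to the swimming speed, approaching a quadratic dependence for small
    attractant gradients, so a relative speed change ``s`` maps to a
    relative drift change ``(1 + s)**e - 1`` with exponent e = 1 or 2.
    """

    relative_speed_change: float
    exponent: int
    relative_drift_change: float


@dataclass(frozen=True)
class ConditionComparison:
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]


def drift_velocity_change(relative_speed_change: float, exponent: int) -> DriftEstimate:
    """Relative drift-velocity change for a relative swim-speed change.

    A 10% speed increase gives +10% drift under the linear dependence
    and +21% under the quadratic (small-gradient) dependence.
    """
    if exponent not in (1, 2):
        raise ValueError("exponent must be 1 (linear) or 2 (quadratic)")
    if not relative_speed_change > -1:
        raise ValueError("relative_speed_change must be > -1")
    change = (1.0 + relative_speed_change) ** exponent - 1.0
    return DriftEstimate(
        relative_speed_change=float(relative_speed_change),
        exponent=exponent,
        relative_drift_change=float(change),
    )


def compare_conditions(
    groups: dict[str, np.ndarray], test: str = "paired-t"
) -> ConditionComparison:
    """Compare condition measurements with a paired t-test (two paired
    vectors) or one-way ANOVA (two or more independent groups)."""
    names = tuple(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if test == "paired-t":
        if len(arrays) != 2 or len(arrays[0]) != len(arrays[1]):
            raise ValueError("paired-t needs exactly two equal-length vectors")
        diff = arrays[0] - arrays[1]
        if len(diff) < 2:
            raise ValueError("paired-t needs at least two pairs")
        if np.ptp(diff) == 0 and diff[0] != 0:
            raise ValueError("degenerate paired differences: zero variance")
        if np.ptp(diff) == 0 and diff[0] == 0:
            return ConditionComparison("paired-t", 0.0, 1.0, names)
        res = stats.ttest_rel(arrays[0], arrays[1])
    elif test == "anova":
        if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
            raise ValueError("anova needs >= 2 groups of >= 2 observations")
        if all(np.ptp(a) == 0 for a in arrays):
            raise ValueError("degenerate groups: zero variance everywhere")
        res = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown test {test!r}; use 'paired-t' or 'anova'")
    return ConditionComparison(test, float(res.statistic), float(res.pvalue), names)


def condition_protocol(ligand: str, strain: StrainProfile, t_intro: float = 0.0) -> syn.LigandProtocol:
    """Ligand protocol for a (ligand, strain) pair under the two-channel
    factorization (sensing -> transient unit; metabolism -> sustained)."""
    transient = 1 if (strain.sensing and ligand in ("glucose", "2Dg")) else 0
    sustained = 1 if (strain.metabolism and ligand == "glucose") else 0
    excursion = 0.0
    if strain.switching and transient:
        excursion = 0.5 if ligand == "glucose" else 0.3
    if ligand == "MB" or (transient + sustained) == 0:
        return syn.LigandProtocol(label=ligand, t_intro=t_intro, recruited_units=0)
    if sustained:
        return syn.LigandProtocol(
            label=ligand, t_intro=t_intro, onset_delay=100.0,
            recruited_units=transient + sustained, dwell=None,
            recruit_stagger=550.0, bias_excursion=excursion,
        )
    onset = 300.0 if ligand == "2Dg" else 100.0
    return syn.LigandProtocol(
        label=ligand, t_intro=t_intro, onset_delay=onset,
        recruited_units=transient, dwell=200.0, bias_excursion=excursion,
    )


def swim_profile_for(ligand: str, strain: StrainProfile, v0: float = 20.1):
    """Population run-speed profile for a condition: baseline scaled by
    the strain, ~25% rise per recruited unit, sustained for metabolized
    ligand and rise-then-return for sensed-only."""
    base = v0 * strain.baseline_factor
    proto = condition_protocol(ligand, strain)
    u = proto.recruited_units
    if u == 0:
        return syn.constant_profile(base)
    peak = base * (1.0 + 0.25 * u)
    if proto.dwell is None:
        return syn.linear_rise_profile(base, peak, 990.0)
    return syn.rise_and_return_profile(base, peak, 390.0, 990.0)


def potential_factor_for(ligand: str, strain: StrainProfile) -> float:
    """Relative membrane-potential factor: metabolized ligand raises it,
    sensed-only ligand leaves it at the buffer level, the ionophore
    control collapses it."""
    if ligand == "CCCP":
        return 0.2
    base = 1.0 if strain.metabolism else 0.55
    if ligand == "glucose" and strain.metabolism:
        return base * 1.3
    return base


@dataclass
class ExperimentConfig:
    """Configuration of a full in-silico experiment.

    ``conditions`` is a list of (label, ligand, strain) with unique
    labels; the first condition is the reference for comparisons.
    Analysis thresholds default to the assay values: 0.05 Hz pause band,
    10-sample smoothing window, 0.5 s track filter, half-mean speed
    factor and 4 degree turn threshold for tumbles.
    """

    seed: int = 0
    conditions: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            ("MB", "MB", "WT"),
            ("glucose", "glucose", "WT"),
            ("2Dg", "2Dg", "WT"),
        ]
    )
    t_intro: float = 60.0
    n_motors: int = 12
    motor_duration: float = 900.0
    motor_fps: float = 60.0
    baseline_units: int = 4
    unit_increment: float = 1.5
    angle_noise_sd: float = 0.05
    n_tracks: int = 2500
    swim_fps: float = 21.0
    swim_bin_edges: tuple[float, ...] = (0.0, 330.0, 660.0, 990.0)
    n_rg_samples: int = 18
    rg_noise_sd: float = 0.05
    min_step: float = 0.5
    min_segment: float = 60.0
    min_track_duration: float = 0.5
    tumble_speed_factor: float = 0.5
    tumble_angle_threshold: float = 4.0
    response_threshold: float = 0.08

    def __post_init__(self):
        labels = [c[0] for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        for _, _, strain in self.conditions:
            if strain not in STRAINS:
                raise ValueError(f"unknown strain {strain!r}; known: {sorted(STRAINS)}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "conditions" in data:
            data["conditions"] = [tuple(c) for c in data["conditions"]]
        if "swim_bin_edges" in data:
            data["swim_bin_edges"] = tuple(data["swim_bin_edges"])
        return cls(**data)


def _classify_response(peak: float, final: float, thr: float) -> str:
    if final >= 1.0 + thr:
        return "sustained"
    if peak >= 1.0 + thr and final < 1.0 + thr / 2.0:
        return "transient"
    return "none"


def _analyze_condition(label, ligand, strain, cfg, child_seeds):
    """Simulate and analyze one condition; returns (summary, paired raw
    values used later for cross-condition comparisons)."""
    proto = condition_protocol(ligand, strain, t_intro=cfg.t_intro)
    t_pre = [0.3 * cfg.t_intro, 0.7 * cfg.t_intro]
    t_post5 = cfg.t_intro + 300.0   # 5 min after introduction
    t_post10 = cfg.t_intro + 600.0  # 10 min
    timepoints = tuple(t_pre + [t_post5, t_post10])

    per_motor = {"speed": [], "bias": [], "steps": [], "norm_int_5": [],
                 "norm_int_10": [], "est_steps_per_rev": []}
    for m in range(cfg.n_motors):
        mseed = int(child_seeds[m])
        params = syn.MotorSimParams(
            duration=cfg.motor_duration, fps=cfg.motor_fps,
            baseline_units=max(1, round(cfg.baseline_units * strain.baseline_factor)),
            unit_increment=cfg.unit_increment,
            angle_noise_sd=cfg.angle_noise_sd,
            ccw_to_cw_rate=0.25 if strain.switching else 0.0,
            cw_to_ccw_rate=1.25 if strain.switching else 0.0,
            seed=mseed,
        )
        track, truth = syn.simulate_tethered(params, proto)
        angles = teth.compute_orientation(track)
        series = teth.compute_rotation_rate(angles, track.fps)
        per_motor["speed"].append(teth.mean_ccw_speed(series))
        per_motor["bias"].append(teth.compute_bias(series))
        steps = teth.detect_steps(series, min_step=cfg.min_step, min_segment=cfg.min_segment)
        per_motor["steps"].append(
            [{"t": e.t, "delta": e.delta, "pre": e.pre_level, "post": e.post_level}
             for e in steps]
        )
        try:
            rev = teth.revolution_variance(angles, k=1)
            per_motor["est_steps_per_rev"].append(rev.est_steps_per_rev)
        except teth.InsufficientDataError:
            pass
        spot_params = syn.IntensitySimParams(
            gain=50.0, background_mean=200.0, noise_sd=5.0,
            timepoints=timepoints, seed=mseed + 1,
        )
        spots = syn.simulate_spot_series(spot_params, truth)
        spots = ip.normalize_series(spots, t_intro=cfg.t_intro)
        per_motor["norm_int_5"].append(float(spots.normalized[2]))
        per_motor["norm_int_10"].append(float(spots.normalized[3]))

    swim_params = syn.SwimSimParams(
        n_tracks=cfg.n_tracks, fps=cfg.swim_fps,
        speed_profile=swim_profile_for(ligand, strain),
        seed=int(child_seeds[cfg.n_motors]),
    )
    tracks, _ = syn.simulate_swim_population(swim_params, proto)
    tracks = swim.filter_tracks(tracks, cfg.min_track_duration)
    bins = swim.population_run_speed(
        tracks, np.asarray(cfg.swim_bin_edges),
        cfg.tumble_speed_factor, cfg.tumble_angle_threshold,
    )
    bin_means = [b.mean_run_speed for b in bins]

    rg_rng = np.random.default_rng(int(child_seeds[cfg.n_motors + 1]))
    pot = potential_factor_for(ligand, strain)
    rg = [
        syn.simulate_rg(pot, size_factor=float(rg_rng.lognormal(0.0, 0.2)),
                        noise_sd=cfg.rg_noise_sd, rng=rg_rng)
        for _ in range(cfg.n_rg_samples)
    ]

    peak_i = float(max(np.mean(per_motor["norm_int_5"]), np.mean(per_motor["norm_int_10"])))
    final_i = float(np.mean(per_motor["norm_int_10"]))
    first, last = bin_means[0], bin_means[-1]
    peak_v = max(bin_means)
    rel_speed_change = (peak_v - first) / first if first > 0 else float("nan")

    summary = {
        "ligand": ligand,
        "strain": strain.label,
        "tethered": {
            "mean_ccw_speed_hz": float(np.mean(per_motor["speed"])),
            "ccw_bias": float(np.mean(per_motor["bias"])),
            "mean_est_steps_per_rev": float(np.mean(per_motor["est_steps_per_rev"]))
            if per_motor["est_steps_per_rev"] else None,
            "steps_first_motor": per_motor["steps"][0],
        },
        "intensity": {
            "normalized_5min": float(np.mean(per_motor["norm_int_5"])),
            "normalized_10min": float(np.mean(per_motor["norm_int_10"])),
            "response_class": _classify_response(peak_i, final_i, cfg.response_threshold),
        },
        "swim": {
            "bin_edges_s": list(map(float, cfg.swim_bin_edges)),
            "bin_mean_run_speed_um_s": [float(v) for v in bin_means],
            "bin_sem": [float(b.sem) for b in bins],
            "bin_n_runs": [b.n_runs for b in bins],
            "bin_n_cells": [b.n_cells for b in bins],
            "relative_speed_change": float(rel_speed_change),
            "response_class": _classify_response(
                peak_v / first, last / first, cfg.response_threshold
            ) if first > 0 else "none",
        },
        "rg": {"mean_ratio": float(np.mean([m.ratio for m in rg]))},
        "drift": {
            "linear_pct": float(100.0 * drift_velocity_change(rel_speed_change, 1).relative_drift_change),
            "quadratic_pct": float(100.0 * drift_velocity_change(rel_speed_change, 2).relative_drift_change),
        },
    }
    raw = {
        "norm_int_10": per_motor["norm_int_10"],
        "rg_ratios": [m.ratio for m in rg],
        "peak_bin_runs": None,  # filled below if needed
    }
    return summary, raw


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run the full in-silico experiment and return the report dict.

    Deterministic given ``config.seed``: two invocations write
    byte-identical JSON. When ``out_dir`` is given the report is written
    to ``report.json`` and per-condition swim statistics to
    ``swim_bins.csv``.
    """
    root_ss = np.random.SeedSequence(config.seed)
    cond_seeds = root_ss.generate_state(len(config.conditions) * 64, dtype=np.uint32)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": int(config.seed),
        "conditions": {},
        "comparisons": {},
        "drift_example": {
            "relative_speed_change": 0.10,
            "linear_pct": 100.0 * drift_velocity_change(0.10, 1).relative_drift_change,
            "quadratic_pct": 100.0 * drift_velocity_change(0.10, 2).relative_drift_change,
        },
    }
    raws = {}
    for i, (label, ligand, strain_name) in enumerate(config.conditions):
        strain = STRAINS[strain_name]
        seeds = cond_seeds[i * 64 : (i + 1) * 64]
        summary, raw = _analyze_condition(label, ligand, strain, config, seeds)
        report["conditions"][label] = summary
        raws[label] = raw

    ref = config.conditions[0][0]
    for label, _, _ in config.conditions[1:]:
        cmp_t = compare_conditions(
            {label: np.asarray(raws[label]["norm_int_10"]),
             ref: np.asarray(raws[ref]["norm_int_10"])},
            test="paired-t",
        )
        cmp_rg = compare_conditions(
            {label: np.asarray(raws[label]["rg_ratios"]),
             ref: np.asarray(raws[ref]["rg_ratios"])},
            test="anova",
        )
        report["comparisons"][f"{label}_vs_{ref}"] = {
            "intensity_10min_paired_t": {"statistic": cmp_t.statistic, "p_value": cmp_t.p_value},
            "rg_anova": {"statistic": cmp_rg.statistic, "p_value": cmp_rg.p_value},
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        )
        rows = ["condition,bin_start,bin_end,mean_run_speed,sem,n_runs,n_cells"]
        for label, cond in report["conditions"].items():
            s = cond["swim"]
            for j in range(len(s["bin_mean_run_speed_um_s"])):
                rows.append(
                    f"{label},{s['bin_edges_s'][j]},{s['bin_edges_s'][j + 1]},"
                    f"{s['bin_mean_run_speed_um_s'][j]},{s['bin_sem'][j]},"
                    f"{s['bin_n_runs'][j]},{s['bin_n_cells'][j]}"
                )
        (out / "swim_bins.csv").write_text("\n".join(rows) + "\n")
    return report
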