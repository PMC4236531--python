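"""Capability gaps, weakness sweeps, tolerance levels and ID-vs-AAN sizing.

The capability gap at a DOF is the task's net joint moment minus the
moment the (possibly weakened) muscles generate; in the static
optimization it is exactly the moment carried by that DOF's ideal moment
actuator.  Sweeping simulated weakness from 0 to 100% of maximal
isometric force yields, per activity and DOF, the lowest weakness level
at which a gap appears (the weakness tolerance) and the peak assistive
moment/power an exoskeleton must supply — the assistance-as-needed (AAN)
sizing, contrasted with sizing from the full inverse-dynamics (ID) task
moment.

All reported moments and powers are mass-normalized (Nm/kg, W/kg).
Because the reserves are quadratically costly rather than forbidden,
they carry an algebraically tiny moment even at full strength; "a gap
exists" therefore uses a detection threshold (default 0.01 Nm/kg, about
1 Nm for a 100 kg user).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import TrialData, joint_power, normalize_by_mass
from .model import MusculoskeletalModel, WeaknessLevel, apply_weakness
from .static_opt import TrialSolution, solve_trial

__all__ = [
    "DEFAULT_GAP_THRESHOLD",
    "DEFAULT_WEAKNESS_LEVELS",
    "CapabilityGapSeries",
    "WeaknessSweepResult",
    "capability_gap",
    "weakness_sweep",
    "detect_gap",
    "tolerance_level",
    "max_requirements",
    "id_vs_aan",
    "build_report",
    "tolerance_report",
]

DEFAULT_GAP_THRESHOLD = 0.01  # Nm/kg
DEFAULT_WEAKNESS_LEVELS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass
class CapabilityGapSeries:
    """Per-frame gap, capability and task moment for one DOF at one weakness."""

    dof: str
    weakness: WeaknessLevel
    time: np.ndarray
    percent_cycle: np.ndarray
    task_moment: np.ndarray  # Nm/kg
    gap_moment: np.ndarray  # Nm/kg (reserve moment)
    capability_moment: np.ndarray  # Nm/kg (= task - gap)
    gap_power: np.ndarray  # W/kg
    angular_velocity: np.ndarray  # rad/s


@dataclass
class WeaknessSweepResult:
    """Gap series for every DOF at every weakness level of one activity."""

    activity: str
    levels: Sequence[WeaknessLevel]
    series: Mapping[float, Mapping[str, CapabilityGapSeries]]
    trial: TrialData

    def get(self, level: float, dof: str) -> CapabilityGapSeries:
        return self.series[float(level)][dof]

    @property
    def dof_names(self) -> list[str]:
        first = self.series[float(self.levels[0].fraction)]
        return list(first.keys())


def capability_gap(
    solutions: TrialSolution, trial: TrialData, dof: str, weakness: WeaknessLevel | None = None
) -> CapabilityGapSeries:
    """Gap series for one DOF: reserve moment, mass-normalized.

    The gap is ``tau0 * a_t`` per frame; the muscle capability is the
    task moment minus the gap; gap power is gap moment times the joint
    angular velocity.
    """
    if dof not in solutions.dof_names:
        raise KeyError(f"no reserve for DOF {dof!r}")
    if solutions.n_frames != trial.n_frames:
        raise ValueError("solutions do not align with trial frames")
    k = list(solutions.dof_names).index(dof)
    kt = trial.dof_index(dof)
    gap_nm = solutions.reserve_moments[:, k]
    task = normalize_by_mass(trial.net_moments[:, kt], trial.body_mass)
    gap = normalize_by_mass(gap_nm, trial.body_mass)
    omega = trial.angular_velocities[:, kt]
    return CapabilityGapSeries(
        dof=dof,
        weakness=weakness if weakness is not None else WeaknessLevel(0.0),
        time=trial.time.copy(),
        percent_cycle=trial.percent_cycle.copy(),
        task_moment=task,
        gap_moment=gap,
        capability_moment=task - gap,
        gap_power=joint_power(gap, omega),
        angular_velocity=omega.copy(),
    )


def weakness_sweep(
    model: MusculoskeletalModel,
    trial: TrialData,
    levels: Sequence[float] = DEFAULT_WEAKNESS_LEVELS,
    reserve_optimal_moment: float = 1.0,
) -> WeaknessSweepResult:
    """Apply each weakness level, re-solve the trial, collect gap series."""
    wlevels = [WeaknessLevel(float(l)) for l in levels]
    out: dict[float, dict[str, CapabilityGapSeries]] = {}
    for w in wlevels:
        weak = apply_weakness(model, w)
        try:
            sol = solve_trial(weak, trial, reserve_optimal_moment=reserve_optimal_moment)
        except RuntimeError as exc:
            raise RuntimeError(f"weakness level {w.fraction:.0%}: {exc}") from exc
        out[w.fraction] = {
            dof: capability_gap(sol, trial, dof, weakness=w) for dof in model.dof_names
        }
    return WeaknessSweepResult(activity=trial.activity, levels=wlevels, series=out, trial=trial)


def detect_gap(
    series: CapabilityGapSeries,
    threshold: float = DEFAULT_GAP_THRESHOLD,
    direction: str | None = None,
) -> tuple[bool, np.ndarray]:
    """Whether a gap exceeds the threshold, and at which frames.

    ``direction`` restricts detection to positive or negative gap
    moments (e.g. plantarflexion vs dorsiflexion deficit); ``None`` uses
    the magnitude.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if direction == "positive":
        mask = series.gap_moment > threshold
    elif direction == "negative":
        mask = series.gap_moment < -threshold
    elif direction is None:
        mask = np.abs(series.gap_moment) > threshold
    else:
        raise ValueError("direction must be 'positive', 'negative' or None")
    idx = np.nonzero(mask)[0]
    return bool(idx.size), idx


def tolerance_level(
    sweep: WeaknessSweepResult,
    dof: str,
    direction: str | None = None,
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> WeaknessLevel | None:
    """Lowest swept weakness level with a detected gap; ``None`` if never."""
    if len(sweep.levels) < 2:
        raise ValueError("sweep must contain at least two levels")
    for w in sweep.levels:
        found, _ = detect_gap(sweep.get(w.fraction, dof), threshold, direction)
        if found:
            return w
    return None


def max_requirements(trial: TrialData) -> pd.DataFrame:
    """Direction-resolved peak task moments (Nm/kg) and powers (W/kg) per DOF."""
    if trial.n_frames == 0:
        raise ValueError("empty trial")
    rows = []
    moments = normalize_by_mass(trial.net_moments, trial.body_mass)
    powers = normalize_by_mass(
        joint_power(trial.net_moments, trial.angular_velocities), trial.body_mass
    )
    for k, dof in enumerate(trial.dof_names):
        m = moments[:, k]
        p = powers[:, k]
        rows.append(
            {
                "activity": trial.activity,
                "dof": dof,
                "max_positive_moment": float(np.max(np.maximum(m, 0.0))),
                "max_negative_moment": float(np.max(np.maximum(-m, 0.0))),
                "max_positive_power": float(np.max(np.maximum(p, 0.0))),
                "max_negative_power": float(np.max(np.maximum(-p, 0.0))),
            }
        )
    return pd.DataFrame(rows)


def id_vs_aan(
    sweep: WeaknessSweepResult,
    dof: str,
    level: float,
    direction: str = "positive",
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> dict:
    """Exoskeleton sizing comparison at one weakness level.

    ``id_peak`` is the peak task moment of the chosen direction (sizing
    from inverse dynamics alone); ``aan_peak`` is the peak capability-gap
    moment at this weakness level (assistance as needed);
    ``aan_support_fraction`` is the percentage of the cycle during which
    the gap exceeds the detection threshold.
    """
    if float(level) not in sweep.series:
        raise KeyError(f"level {level} not in sweep")
    series = sweep.get(level, dof)
    s = 1.0 if direction == "positive" else -1.0
    id_peak = float(np.max(np.maximum(s * series.task_moment, 0.0)))
    aan_peak = float(np.max(np.maximum(s * series.gap_moment, 0.0)))
    _, idx = detect_gap(series, threshold, direction)
    support = 100.0 * idx.size / series.gap_moment.shape[0]
    return {
        "dof": dof,
        "direction": direction,
        "weakness": float(level),
        "id_peak": id_peak,
        "aan_peak": aan_peak,
        "aan_support_fraction": support,
    }


def build_report(
    sweeps: Mapping[str, WeaknessSweepResult],
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> pd.DataFrame:
    """Long-format report: one row per (activity, dof, direction, level)."""
    rows = []
    for activity, sweep in sweeps.items():
        for w in sweep.levels:
            for dof in sweep.dof_names:
                series = sweep.get(w.fraction, dof)
                for direction, s in (("positive", 1.0), ("negative", -1.0)):
                    gap = np.maximum(s * series.gap_moment, 0.0)
                    gpow = np.maximum(s * series.gap_power, 0.0)
                    task = np.maximum(s * series.task_moment, 0.0)
                    found, _ = detect_gap(series, threshold, direction)
                    rows.append(
                        {
                            "activity": activity,
                            "dof": dof,
                            "direction": direction,
                            "weakness_level": w.fraction,
                            "peak_gap_moment": float(np.max(gap)),
                            "peak_gap_power": float(np.max(gpow)),
                            "peak_task_moment": float(np.max(task)),
                            "gap_detected": found,
                        }
                    )
    return pd.DataFrame(rows)


def tolerance_report(
    sweeps: Mapping[str, WeaknessSweepResult],
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> pd.DataFrame:
    """Per (activity, dof, direction): weakness tolerance and maxima.

    The tolerance is the lowest swept weakness level with a detected gap
    (NaN if the demand is met at every level); maxima are the peak task
    moment/power and the peak gap moment/power at full weakness.
    """
    rows = []
    for activity, sweep in sweeps.items():
        maxreq = max_requirements(sweep.trial).set_index("dof")
        for dof in sweep.dof_names:
            for direction in ("positive", "negative"):
                tol = tolerance_level(sweep, dof, direction, threshold)
                full = sweep.get(sweep.levels[-1].fraction, dof)
                s = 1.0 if direction == "positive" else -1.0
                rows.append(
                    {
                        "activity": activity,
                        "dof": dof,
                        "direction": direction,
                        "tolerance_weakness": np.nan if tol is None else tol.fraction,
                        "max_task_moment": float(
                            maxreq.loc[dof, f"max_{direction}_moment"]
                        ),
                        "max_task_power": float(maxreq.loc[dof, f"max_{direction}_power"]),
                        "max_gap_moment_full_weakness": float(
                            np.max(np.maximum(s * full.gap_moment, 0.0))
                        ),
                        "max_gap_power_full_weakness": float(
                            np.max(np.maximum(s * full.gap_power, 0.0))
                        ),
                    }
                )
    return pd.DataFrame(rows)
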