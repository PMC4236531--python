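"""Synthetic activities-of-daily-living trials and EMG-like signals.

The generator emulates single-leg sagittal-plane trials of the five
activities the analysis targets: gait, stair ascent, stair descent,
sit-to-stand and stand-to-sit.  Joint-angle trajectories are parametric
— truncated Fourier series for the cyclic activities, logistic
transitions for the chair tasks — so angular velocities and
accelerations are available in closed form.  Net joint moments follow
smooth bump-shaped profiles with peak mass-normalized magnitudes set per
DOF (order 0.1-1.7 Nm/kg, stair tasks most demanding at the ankle).

Dynamical consistency is enforced by construction: for every frame a
ground-reaction-style point force on the foot is solved from a small
linear system so that planar inverse dynamics of the segment chain
reproduces the target moments.  Re-running inverse dynamics on the
generated kinematics and external load therefore returns the trial's
``net_moments`` to round-off.

Trial-to-trial variability (``noise_sd``) perturbs the trajectory
coefficients and moment scales multiplicatively with seeded Gaussian
draws, keeping every realization smooth and dynamically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy import signal as sps

from .kinetics import ACTIVITIES, SegmentChain, TrialData, inverse_dynamics_planar
from .model import MusculoskeletalModel
from .static_opt import TrialSolution

__all__ = [
    "ADLProfile",
    "SyntheticEMG",
    "load_profiles",
    "default_profile",
    "generate_trial",
    "generate_emg",
    "CHAIN_DOF_SIGNS",
    "CHAIN_DOF_OFFSETS",
]

# Mapping between model DOF conventions (hip/knee extension positive,
# ankle plantarflexion positive) and the chain's counterclockwise
# relative joint angles (zero = hanging straight down, foot at right
# angle to the shank):  theta_chain = sign * q_dof + offset.
CHAIN_DOF_SIGNS = {"hip": -1.0, "knee": 1.0, "ankle": -1.0}
CHAIN_DOF_OFFSETS = {"hip": 0.0, "knee": 0.0, "ankle": np.pi / 2}


@dataclass
class ADLProfile:
    """Parametric description of one synthetic activity trial.

    ``angle_params`` maps DOF name to either a Fourier parameterization
    (``type: fourier`` with mean ``a0`` and harmonic coefficient lists
    ``an``/``bn``, rad) or a logistic transition (``type: logistic`` with
    ``start``, ``end`` angles, relative ``center`` and ``steepness``).
    ``moment_params`` maps DOF name to ``{scale, bumps}`` where ``scale``
    is the peak mass-normalized moment target (Nm/kg) and each bump is
    ``[center_fraction, width_fraction, weight]`` of a Gaussian lobe of
    the moment shape (periodic wrap for cyclic activities).
    """

    activity: str
    duration: float
    sampling_rate: float
    cyclic: bool
    angle_params: Mapping[str, Mapping]
    moment_params: Mapping[str, Mapping]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticEMG:
    """Raw EMG-like signal with the ground-truth activation that drove it."""

    muscle: str
    raw: np.ndarray  # arbitrary units, at self.fs
    fs: float  # Hz
    time: np.ndarray  # sample times of raw
    true_activation: np.ndarray  # per trial frame, dimensionless
    trial_time: np.ndarray  # trial frame times

    def __post_init__(self):
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("raw signal must be finite")
        if np.any(self.true_activation < -1e-9) or np.any(self.true_activation > 1 + 1e-9):
            raise ValueError("true_activation must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trajectory primitives


def _fourier_series(t, T, a0, an, bn, deriv=0):
    """Value or time-derivative of a truncated Fourier series, closed form."""
    out = np.full_like(t, a0 if deriv == 0 else 0.0, dtype=float)
    for n, (a, b) in enumerate(zip(an, bn), start=1):
        w = 2.0 * np.pi * n / T
        ph = w * t
        if deriv == 0:
            out += a * np.cos(ph) + b * np.sin(ph)
        elif deriv == 1:
            out += -a * w * np.sin(ph) + b * w * np.cos(ph)
        elif deriv == 2:
            out += -a * w**2 * np.cos(ph) - b * w**2 * np.sin(ph)
    return out


def _logistic(t, T, start, end, center, steepness, deriv=0):
    """Smooth sigmoid transition from ``start`` to ``end`` over the trial."""
    x = steepness * (t / T - center)
    sig = 1.0 / (1.0 + np.exp(-x))
    if deriv == 0:
        return start + (end - start) * sig
    dsig = sig * (1.0 - sig) * steepness / T
    if deriv == 1:
        return (end - start) * dsig
    d2 = dsig * (1.0 - 2.0 * sig) * steepness / T
    return (end - start) * d2


def _angle_traj(params, t, T, deriv=0):
    kind = params.get("type", "fourier")
    if kind == "fourier":
        return _fourier_series(
            t, T, float(params["a0"]), list(params.get("an", [])), list(params.get("bn", [])), deriv
        )
    if kind == "logistic":
        return _logistic(
            t,
            T,
            float(params["start"]),
            float(params["end"]),
            float(params.get("center", 0.5)),
            float(params.get("steepness", 10.0)),
            deriv,
        )
    raise ValueError(f"unknown trajectory type {kind!r}")


def _moment_shape(bumps, frac, cyclic):
    """Sum of Gaussian lobes over cycle fraction, periodic if cyclic."""
    shape = np.zeros_like(frac)
    for center, width, weight in bumps:
        if cyclic:
            for wrap in (-1.0, 0.0, 1.0):
                shape += weight * np.exp(-(((frac - center + wrap) / width) ** 2))
        else:
            shape += weight * np.exp(-(((frac - center) / width) ** 2))
    return shape


def _perturb(params: Mapping, rng: np.random.Generator, noise_sd: float) -> dict:
    """Multiplicative Gaussian jitter of all numeric trajectory parameters."""
    out = {}
    for key, val in params.items():
        if key in ("type",):
            out[key] = val
        elif isinstance(val, (list, tuple)):
            out[key] = [v * (1.0 + noise_sd * rng.standard_normal()) for v in val]
        elif isinstance(val, (int, float)):
            out[key] = val * (1.0 + noise_sd * rng.standard_normal())
        else:
            out[key] = val
    return out


# ---------------------------------------------------------------------------
# Trial generation


def _build_chain(model: MusculoskeletalModel) -> SegmentChain:
    return SegmentChain(segments=list(model.segment_properties))


def generate_trial(
    profile: ADLProfile,
    model: MusculoskeletalModel,
    return_chain: bool = False,
):
    """Generate one dynamically consistent synthetic trial.

    Angles and their derivatives come from the profile's closed-form
    trajectories; net moments equal the profile's bump-shaped profiles
    scaled to ``moment_scale`` (Nm/kg) peaks, realized by a per-frame
    ground-reaction point force solved so that planar inverse dynamics
    reproduces them.  Bit-reproducible for a given seed; cyclic
    activities start and end at the same posture.

    With ``return_chain=True`` also returns the ``SegmentChain`` carrying
    the solved external load, for consistency checks.
    """
    dof_names = model.dof_names
    missing = set(dof_names) - set(profile.angle_params)
    if missing or set(dof_names) - set(profile.moment_params):
        raise ValueError(f"profile does not cover model DOFs {sorted(missing)}")
    rng = np.random.default_rng(profile.seed)
    T = profile.duration
    n = int(round(T * profile.sampling_rate)) + 1
    t = np.linspace(0.0, T, n)
    frac = t / T

    q = np.zeros((n, len(dof_names)))
    qd = np.zeros_like(q)
    qdd = np.zeros_like(q)
    tau_des = np.zeros_like(q)
    for k, dof in enumerate(dof_names):
        ap = _perturb(profile.angle_params[dof], rng, profile.noise_sd)
        q[:, k] = _angle_traj(ap, t, T, 0)
        qd[:, k] = _angle_traj(ap, t, T, 1)
        qdd[:, k] = _angle_traj(ap, t, T, 2)
        mp = profile.moment_params[dof]
        scale = float(mp["scale"]) * (1.0 + profile.noise_sd * rng.standard_normal())
        shape = _moment_shape(mp["bumps"], frac, profile.cyclic)
        peak = np.max(np.abs(shape))
        if peak > 0:
            shape = shape / peak
        tau_des[:, k] = shape * scale * model.body_mass

    # chain-frame kinematics
    signs = np.array([CHAIN_DOF_SIGNS[d] for d in dof_names])
    offsets = np.array([CHAIN_DOF_OFFSETS[d] for d in dof_names])
    cq = signs[None, :] * q + offsets[None, :]
    cqd = signs[None, :] * qd
    cqdd = signs[None, :] * qdd

    chain = _build_chain(model)
    tau_gi_chain = inverse_dynamics_planar(chain, cq, cqd, cqdd)

    # joint positions for the external-load solve
    theta = np.cumsum(cq, axis=1)
    d = np.stack([np.sin(theta), -np.cos(theta)], axis=-1)
    lengths = np.array([s.length for s in chain.segments])
    joint_pos = np.zeros((n, len(dof_names), 2))
    for j in range(1, len(dof_names)):
        joint_pos[:, j, :] = joint_pos[:, j - 1, :] + lengths[j - 1] * d[:, j - 1, :]
    foot_com = joint_pos[:, -1, :] + chain.segments[-1].com * d[:, -1, :]

    # Solve per frame for (Fx, Fy, px*Fy) so that the external-force
    # moment contribution closes the gap to the target chain moments.
    delta_chain = signs[None, :] * tau_des - tau_gi_chain
    force = np.zeros((n, 2))
    point = np.zeros((n, 2))
    achieved_ext = np.zeros_like(delta_chain)
    for i in range(n):
        py = foot_com[i, 1]
        A = np.column_stack(
            [py - joint_pos[i, :, 1], joint_pos[i, :, 0], -np.ones(len(dof_names))]
        )
        x, *_ = np.linalg.lstsq(A, delta_chain[i], rcond=None)
        u, v, w = x
        force[i] = (u, v)
        point[i] = (w / v if abs(v) > 1e-9 else foot_com[i, 0], py)
        achieved_ext[i] = A @ x

    chain.external_force = force
    chain.external_point = point
    net_moments = signs[None, :] * (tau_gi_chain + achieved_ext)

    trial = TrialData(
        activity=profile.activity,
        time=t,
        dof_names=list(dof_names),
        angles=q,
        angular_velocities=qd,
        net_moments=net_moments,
        body_mass=model.body_mass,
    )
    if return_chain:
        return trial, chain
    return trial


# ---------------------------------------------------------------------------
# Synthetic EMG


def generate_emg(
    solutions: TrialSolution,
    muscle: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 1000.0,
) -> SyntheticEMG:
    """EMG-like raw signal whose envelope follows a muscle's activation.

    A zero-mean unit-RMS carrier — a sinusoid whose instantaneous
    frequency wanders randomly across the 20-400 Hz surface-EMG band —
    is amplitude-modulated by the activation time series upsampled to
    ``fs``; Gaussian noise with standard deviation ``noise_sd`` times the
    peak activation is added on top.  The carrier's rectified, low-passed
    amplitude is constant, so the processed envelope tracks the
    activation itself rather than the carrier realization.  Seeded and
    reproducible; different seeds give different carriers with the same
    expected envelope.
    """
    if muscle not in solutions.muscle_names:
        raise KeyError(f"unknown muscle {muscle!r}")
    idx = list(solutions.muscle_names).index(muscle)
    a = solutions.activations[:, idx]
    t = solutions.time
    t_up = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
    a_up = np.interp(t_up, t, a)

    rng = np.random.default_rng(seed)
    # instantaneous frequency: slow random wander inside the EMG band
    wander = sps.sosfiltfilt(
        sps.butter(2, 1.0, btype="low", fs=fs, output="sos"),
        rng.standard_normal(t_up.shape[0]),
    )
    span = np.ptp(wander)
    wander = (wander - np.min(wander)) / span if span > 0 else np.zeros_like(wander)
    f_inst = 60.0 + 300.0 * wander
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0.0, 2.0 * np.pi)
    carrier = np.sqrt(2.0) * np.sin(phase)
    amax = float(np.max(a_up)) if np.max(a_up) > 0 else 1.0
    raw = a_up * carrier + noise_sd * amax * rng.standard_normal(t_up.shape[0])
    return SyntheticEMG(
        muscle=muscle,
        raw=raw,
        fs=fs,
        time=t_up,
        true_activation=a.copy(),
        trial_time=t.copy(),
    )


# ---------------------------------------------------------------------------
# Shipped fixture profiles


def load_profiles(noise_sd: float = 0.0, seed: int = 0) -> dict[str, ADLProfile]:
    """The shipped fixture profiles for all five activities."""
    text = resources.files("capgap").joinpath("data/profiles.yaml").read_text()
    cfg = yaml.safe_load(text)
    out = {}
    for activity, p in cfg.items():
        out[activity] = ADLProfile(
            activity=activity,
            duration=float(p["duration"]),
            sampling_rate=float(p.get("sampling_rate", 100.0)),
            cyclic=bool(p["cyclic"]),
            angle_params=p["angles"],
            moment_params=p["moments"],
            noise_sd=noise_sd,
            seed=seed,
        )
    return out


def default_profile(activity: str, noise_sd: float = 0.0, seed: int = 0) -> ADLProfile:
    profiles = load_profiles(noise_sd=noise_sd, seed=seed)
    if activity not in profiles:
        raise KeyError(f"no shipped profile for activity {activity!r}")
    return profiles[activity]
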