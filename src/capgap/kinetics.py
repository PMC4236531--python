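"""Task requirements: planar inverse dynamics, joint power, normalization.

The inverse-dynamics chain is a planar open linkage rooted at a fixed
base (the pelvis).  Segment orientations are measured counterclockwise
from the downward vertical, so all joint angles zero means the chain
hangs straight down; gravity acts along -y.  Joint ``i`` connects segment
``i`` to its parent, and the returned moment at joint ``i`` is the
counterclockwise moment the parent exerts on segment ``i`` — the net
joint moment of classic gait analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .model import SegmentProperties

ACTIVITIES = ("gait", "stair_ascent", "stair_descent", "sit_to_stand", "stand_to_sit")

__all__ = [
    "ACTIVITIES",
    "TrialData",
    "SegmentChain",
    "inverse_dynamics_planar",
    "differentiate",
    "joint_power",
    "normalize_by_mass",
    "resample_to_cycle",
]


@dataclass
class TrialData:
    """Time-stamped kinematics and net joint moments for one activity trial.

    ``angles``, ``angular_velocities`` and ``net_moments`` are
    (frames x DOFs) arrays in the order of ``dof_names``; moments are raw
    newton-meters (mass normalization is applied at reporting time).
    """

    activity: str
    time: np.ndarray
    dof_names: Sequence[str]
    angles: np.ndarray
    angular_velocities: np.ndarray
    net_moments: np.ndarray
    body_mass: float
    percent_cycle: np.ndarray | None = None

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.angular_velocities = np.atleast_2d(np.asarray(self.angular_velocities, dtype=float))
        self.net_moments = np.atleast_2d(np.asarray(self.net_moments, dtype=float))
        n = self.time.shape[0]
        k = len(self.dof_names)
        for nm, arr in (
            ("angles", self.angles),
            ("angular_velocities", self.angular_velocities),
            ("net_moments", self.net_moments),
        ):
            if arr.shape != (n, k):
                raise ValueError(f"{nm} must have shape ({n}, {k}), got {arr.shape}")
        dt = np.diff(self.time)
        if n >= 2 and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("time must be strictly increasing with a uniform step")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.percent_cycle is None:
            span = self.time[-1] - self.time[0] if n > 1 else 1.0
            self.percent_cycle = 100.0 * (self.time - self.time[0]) / span
        self.percent_cycle = np.asarray(self.percent_cycle, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def dof_index(self, name: str) -> int:
        return list(self.dof_names).index(name)


@dataclass
class SegmentChain:
    """Planar open chain for inverse dynamics, proximal to distal.

    ``external_load`` holds an optional ground-reaction-style point force
    on the distal segment: per-frame force (frames x 2) and application
    point (frames x 2) in the base frame.
    """

    segments: Sequence[SegmentProperties]
    gravity: float = 9.81
    external_force: np.ndarray | None = None
    external_point: np.ndarray | None = None
    base_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError("chain needs at least one segment")

    @property
    def n_joints(self) -> int:
        return len(self.segments)


def _chain_geometry(chain: SegmentChain, q: np.ndarray, qd: np.ndarray, qdd: np.ndarray):
    """Absolute angles, joint/COM positions and COM accelerations, per frame."""
    q, qd, qdd = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (q, qd, qdd))
    F, J = q.shape
    if J != chain.n_joints:
        raise ValueError(f"expected {chain.n_joints} joint columns, got {J}")
    theta = np.cumsum(q, axis=1)
    thetad = np.cumsum(qd, axis=1)
    thetadd = np.cumsum(qdd, axis=1)
    # direction of each segment (from downward vertical, CCW positive)
    d = np.stack([np.sin(theta), -np.cos(theta)], axis=-1)  # (F, J, 2)
    e = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # d(theta) derivative dir
    lengths = np.array([s.length for s in chain.segments])
    coms = np.array([s.com for s in chain.segments])

    joint_pos = np.zeros((F, J, 2))
    joint_pos[:, 0, :] = np.asarray(chain.base_origin, dtype=float)
    for j in range(1, J):
        joint_pos[:, j, :] = joint_pos[:, j - 1, :] + lengths[j - 1] * d[:, j - 1, :]
    com_pos = joint_pos + coms[None, :, None] * d

    # acceleration of the endpoint of each segment and of each COM
    seg_acc = lengths[None, :, None] * (
        thetadd[..., None] * e - (thetad**2)[..., None] * d
    )  # full-length tip acceleration contribution of each segment
    joint_acc = np.zeros((F, J, 2))
    for j in range(1, J):
        joint_acc[:, j, :] = joint_acc[:, j - 1, :] + seg_acc[:, j - 1, :]
    com_acc = joint_acc + coms[None, :, None] * (
        thetadd[..., None] * e - (thetad**2)[..., None] * d
    )
    return theta, thetadd, joint_pos, com_pos, com_acc


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def inverse_dynamics_planar(
    chain: SegmentChain,
    angles: np.ndarray,
    angular_velocities: np.ndarray,
    angular_accelerations: np.ndarray,
) -> np.ndarray:
    """Net joint moments (frames x joints, Nm) by recursive Newton-Euler.

    Runs the force/moment recursion from the distal segment to the base,
    including gravity and the chain's external point load on the distal
    segment.  In the static, unloaded limit it reduces to the closed-form
    gravitational moments ``sum_i m_i g (horizontal COM offset)``.
    """
    q = np.atleast_2d(np.asarray(angles, dtype=float))
    qd = np.atleast_2d(np.asarray(angular_velocities, dtype=float))
    qdd = np.atleast_2d(np.asarray(angular_accelerations, dtype=float))
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd)) and np.all(np.isfinite(qdd))):
        raise ValueError("non-finite kinematics")
    if q.shape != qd.shape or q.shape != qdd.shape:
        raise ValueError("kinematics arrays must share one shape")
    F, J = q.shape
    _, thetadd, joint_pos, com_pos, com_acc = _chain_geometry(chain, q, qd, qdd)

    g_vec = np.array([0.0, -chain.gravity])
    masses = np.array([s.mass for s in chain.segments])
    inertias = np.array([s.inertia for s in chain.segments])

    f_ext = np.zeros((F, 2))
    p_ext = np.zeros((F, 2))
    if chain.external_force is not None:
        f_ext = np.atleast_2d(np.asarray(chain.external_force, dtype=float))
        p_ext = np.atleast_2d(np.asarray(chain.external_point, dtype=float))
        if f_ext.shape != (F, 2) or p_ext.shape != (F, 2):
            raise ValueError("external load must be (frames x 2) force and point arrays")

    moments = np.zeros((F, J))
    f_child = np.zeros((F, 2))
    n_child = np.zeros(F)
    for j in range(J - 1, -1, -1):
        on_distal = j == J - 1
        fe = f_ext if on_distal else 0.0
        pe = p_ext
        f_j = masses[j] * (com_acc[:, j, :] - g_vec) + f_child - fe
        n_j = (
            inertias[j] * thetadd[:, j]
            - _cross2(joint_pos[:, j, :] - com_pos[:, j, :], f_j)
            + n_child
        )
        if j < J - 1:
            n_j += _cross2(joint_pos[:, j + 1, :] - com_pos[:, j, :], f_child)
        if on_distal and chain.external_force is not None:
            n_j -= _cross2(pe - com_pos[:, j, :], f_ext)
        moments[:, j] = n_j
        f_child = f_j
        n_child = n_j
    return moments


def differentiate(
    series: np.ndarray,
    dt: float,
    smooth_cutoff_hz: float | None = None,
) -> np.ndarray:
    """Per-frame time derivative: central differences, one-sided at the ends.

    If ``smooth_cutoff_hz`` is given the series is first low-pass filtered
    with a zero-lag 4th-order Butterworth at that cutoff.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if smooth_cutoff_hz is not None:
        fs = 1.0 / dt
        sos = sps.butter(4, smooth_cutoff_hz, btype="low", fs=fs, output="sos")
        series = sps.sosfiltfilt(sos, series, axis=0)
    return np.gradient(series, dt, axis=0)


def joint_power(net_moment: np.ndarray, angular_velocity: np.ndarray) -> np.ndarray:
    """Joint power (W): moment times angular velocity, sign preserved."""
    m = np.asarray(net_moment, dtype=float)
    w = np.asarray(angular_velocity, dtype=float)
    if m.shape != w.shape:
        raise ValueError("moment and angular velocity must have equal shapes")
    return m * w


def normalize_by_mass(values: np.ndarray, body_mass: float) -> np.ndarray:
    """Mass-normalize moments (-> Nm/kg) or powers (-> W/kg)."""
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return np.asarray(values, dtype=float) / body_mass


def resample_to_cycle(trial: TrialData, n_points: int = 101) -> TrialData:
    """Resample a trial to ``n_points`` evenly spaced over 0-100% cycle."""
    pc = np.linspace(0.0, 100.0, n_points)
    t = np.interp(pc, trial.percent_cycle, trial.time)
    # force an exactly uniform grid for the resampled container
    t = np.linspace(trial.time[0], trial.time[-1], n_points)

    def interp_cols(arr):
        return np.column_stack(
            [np.interp(t, trial.time, arr[:, k]) for k in range(arr.shape[1])]
        )

    return TrialData(
        activity=trial.activity,
        time=t,
        dof_names=list(trial.dof_names),
        angles=interp_cols(trial.angles),
        angular_velocities=interp_cols(trial.angular_velocities),
        net_moments=interp_cols(trial.net_moments),
        body_mass=trial.body_mass,
        percent_cycle=pc,
    )
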