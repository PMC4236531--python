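"""Simplified planar musculoskeletal model with Hill-type muscle actuators.

The model is a sagittal-plane lower limb: an ordered set of degrees of
freedom (hip, knee, ankle flexion/extension by default), a set of muscles
with Hill-type active force generation and angle-dependent moment arms,
and the segment inertial properties used by inverse dynamics.

Sign conventions
----------------
Extension moments are positive at the hip and knee; plantarflexion is
positive at the ankle.  Joint angles share the positive direction of their
moments, so joint power is simply moment times angular velocity.  Angles
are radians everywhere inside the package.

Muscle geometry is reduced to polynomial moment arms ``r(q)`` per spanned
DOF.  With a rigid tendon, fiber length follows from the exact polynomial
antiderivative of the moment arm (``dl = -r dq``), so a positive moment
arm combined with an increasing angle shortens the muscle.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DOF",
    "MuscleParams",
    "MuscleState",
    "SegmentProperties",
    "MusculoskeletalModel",
    "WeaknessLevel",
    "force_length",
    "force_velocity",
    "active_force",
    "apply_weakness",
    "moment_arm",
    "muscle_kinematics",
    "max_feasible_moment",
    "load_model",
    "planar9",
]

# Active force-length: Gaussian around the optimal fiber length.
FL_WIDTH = 0.45
# Force-velocity: Hill hyperbola shape factor (a/F0) for shortening and
# the eccentric force plateau for lengthening.
FV_SHAPE = 0.25
FV_ECC_PLATEAU = 1.4
# Slope of the eccentric branch at zero velocity, matched to the
# concentric slope (1 + 1/FV_SHAPE) so the curve is C1 at v = 0.
_FV_ECC_SLOPE = 1.0 + 1.0 / FV_SHAPE


def force_length(lnorm):
    """Active force-length multiplier at normalized fiber length ``lnorm``.

    Gaussian ``exp(-((l - 1)/0.45)^2)``; equals 1 at the optimal length.
    """
    lnorm = np.asarray(lnorm, dtype=float)
    return np.exp(-(((lnorm - 1.0) / FL_WIDTH) ** 2))


def force_velocity(vnorm):
    """Force-velocity multiplier at normalized fiber velocity ``vnorm``.

    ``vnorm`` is fiber velocity over (optimal length x max contraction
    velocity); shortening is negative.  Shortening follows the classic
    Hill hyperbola ``(1 + v) / (1 - v/0.25)``, clamped to 0 at and beyond
    the maximal shortening velocity; lengthening rises smoothly to a
    plateau of 1.4.  Equals 1 at zero velocity.
    """
    vnorm = np.asarray(vnorm, dtype=float)
    conc = np.where(
        vnorm <= -1.0,
        0.0,
        (1.0 + vnorm) / (1.0 - np.minimum(vnorm, 0.0) / FV_SHAPE),
    )
    rise = _FV_ECC_SLOPE / (FV_ECC_PLATEAU - 1.0)
    ecc = FV_ECC_PLATEAU - (FV_ECC_PLATEAU - 1.0) * np.exp(-rise * np.maximum(vnorm, 0.0))
    out = np.where(vnorm < 0.0, conc, ecc)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DOF:
    """A model degree of freedom with a documented sign convention."""

    name: str
    positive_direction_label: str = ""


@dataclass
class MuscleParams:
    """Hill-type muscle actuator parameters.

    Parameters
    ----------
    max_isometric_force : float
        Maximal isometric force F0 in newtons.
    optimal_fiber_length : float
        Fiber length (m) at which active force peaks.  With the rigid
        tendon assumed here this is an effective musculotendon constant.
    max_contraction_velocity : float
        Maximal shortening velocity in optimal fiber lengths per second.
    spanned_dofs : sequence of str
        Names of the DOFs this muscle crosses (two entries for a
        bi-articular muscle).
    moment_arm_coeffs : mapping str -> coefficients
        Per spanned DOF, polynomial coefficients of the moment arm versus
        joint angle, lowest order first (m, m/rad, ...).  The sign encodes
        the action direction in that DOF's positive-moment convention.
    reference_fiber_length : float, optional
        Fiber length at the reference posture (all angles zero); defaults
        to the optimal fiber length.
    """

    name: str
    max_isometric_force: float
    optimal_fiber_length: float
    max_contraction_velocity: float = 10.0
    spanned_dofs: Sequence[str] = field(default_factory=list)
    moment_arm_coeffs: Mapping[str, Sequence[float]] = field(default_factory=dict)
    reference_fiber_length: float | None = None

    def __post_init__(self):
        if self.max_isometric_force < 0:
            raise ValueError(f"{self.name}: max_isometric_force must be >= 0")
        if self.optimal_fiber_length <= 0:
            raise ValueError(f"{self.name}: optimal_fiber_length must be > 0")
        if self.max_contraction_velocity <= 0:
            raise ValueError(f"{self.name}: max_contraction_velocity must be > 0")
        missing = set(self.spanned_dofs) - set(self.moment_arm_coeffs)
        if missing:
            raise ValueError(f"{self.name}: no moment arm coefficients for {sorted(missing)}")
        if self.reference_fiber_length is None:
            self.reference_fiber_length = self.optimal_fiber_length


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous fiber length (m) and velocity (m/s, shortening < 0)."""

    fiber_length: float
    fiber_velocity: float

    def __post_init__(self):
        if not (self.fiber_length > 0):
            raise ValueError("fiber_length must be > 0")


@dataclass(frozen=True)
class SegmentProperties:
    """Inertial properties of one body segment of the planar chain."""

    name: str
    mass: float  # kg
    length: float  # m
    com: float  # distance of the COM from the proximal joint, m
    inertia: float  # about the COM, kg m^2

    def __post_init__(self):
        if self.mass <= 0 or self.length <= 0:
            raise ValueError(f"{self.name}: mass and length must be > 0")


@dataclass
class MusculoskeletalModel:
    """A planar lower-limb model: DOFs, muscles, segments and body mass."""

    dofs: Sequence[DOF]
    muscles: Sequence[MuscleParams]
    segment_properties: Sequence[SegmentProperties]
    body_mass: float
    name: str = "model"

    def __post_init__(self):
        names = [d.name for d in self.dofs]
        if len(set(names)) != len(names):
            raise ValueError("DOF names must be unique")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if len(self.muscles) < 1:
            raise ValueError("model needs at least one muscle")
        for m in self.muscles:
            unknown = set(m.spanned_dofs) - set(names)
            if unknown:
                raise ValueError(f"muscle {m.name} spans unknown DOFs {sorted(unknown)}")

    @property
    def dof_names(self) -> list[str]:
        return [d.name for d in self.dofs]

    def dof(self, name: str) -> DOF:
        for d in self.dofs:
            if d.name == name:
                return d
        raise KeyError(name)


@dataclass(frozen=True)
class WeaknessLevel:
    """Uniform fractional loss of maximal isometric force, in [0, 1]."""

    fraction: float

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("weakness fraction must lie in [0, 1]")


def active_force(params: MuscleParams, state: MuscleState, activation: float) -> float:
    """Active muscle force a * F0 * f_L(l~) * f_V(v~), in newtons.

    ``l~`` is fiber length over optimal length; ``v~`` is fiber velocity
    over (optimal length x max contraction velocity).  Linear in both the
    activation and the maximal isometric force.
    """
    if not (0.0 <= activation <= 1.0):
        raise ValueError("activation must lie in [0, 1]")
    if not (math.isfinite(state.fiber_length) and math.isfinite(state.fiber_velocity)):
        raise ValueError("non-finite muscle state: corrupt kinematics")
    lnorm = state.fiber_length / params.optimal_fiber_length
    vnorm = state.fiber_velocity / (params.optimal_fiber_length * params.max_contraction_velocity)
    return float(
        activation * params.max_isometric_force * force_length(lnorm) * force_velocity(vnorm)
    )


def apply_weakness(model: MusculoskeletalModel, w: WeaknessLevel) -> MusculoskeletalModel:
    """Return a copy of ``model`` with every F0 scaled by ``1 - w.fraction``.

    Scaling F0 scales the whole active force-length and force-velocity
    surface; all other parameters are untouched and the input model is
    not modified.
    """
    scale = 1.0 - w.fraction
    muscles = [
        replace(copy.deepcopy(m), max_isometric_force=m.max_isometric_force * scale)
        for m in model.muscles
    ]
    return replace(model, muscles=muscles)


def _polyval(coeffs: Sequence[float], x: float) -> float:
    return float(np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float)))


def moment_arm(params: MuscleParams, dof: DOF | str, angle: float) -> float:
    """Signed moment arm (m) of the muscle on ``dof`` at ``angle`` (rad).

    Raises ``KeyError`` for a DOF the muscle does not span, which is
    distinct from a zero moment arm.
    """
    name = dof.name if isinstance(dof, DOF) else dof
    if name not in params.moment_arm_coeffs:
        raise KeyError(f"muscle {params.name} does not span DOF {name}")
    return _polyval(params.moment_arm_coeffs[name], angle)


def muscle_kinematics(
    params: MuscleParams,
    angles: Mapping[str, float],
    angular_velocities: Mapping[str, float],
) -> MuscleState:
    """Fiber length and velocity at a posture, from the moment-arm polynomials.

    Length is the reference length minus the exact integral of the moment
    arm from the reference posture (all angles zero) to the current
    angles; velocity is ``-sum_k r_k(q_k) * qdot_k``.
    """
    length = params.reference_fiber_length
    velocity = 0.0
    for dof_name in params.spanned_dofs:
        if dof_name not in angles or dof_name not in angular_velocities:
            raise KeyError(f"missing kinematics for spanned DOF {dof_name}")
        coeffs = np.asarray(params.moment_arm_coeffs[dof_name], dtype=float)
        anti = np.polynomial.polynomial.polyint(coeffs)
        q = float(angles[dof_name])
        length -= float(np.polynomial.polynomial.polyval(q, anti))
        velocity -= _polyval(coeffs, q) * float(angular_velocities[dof_name])
    if not length > 0:
        raise ValueError(
            f"muscle {params.name}: non-positive fiber length {length:.4g} m "
            "(inconsistent model geometry)"
        )
    return MuscleState(fiber_length=length, fiber_velocity=velocity)


def max_feasible_moment(
    model: MusculoskeletalModel,
    dof: DOF | str,
    angles: Mapping[str, float],
    angular_velocities: Mapping[str, float],
    sign: int,
) -> float:
    """Upper bound (Nm) on the muscle-generated moment of one sign at a posture.

    Sums ``active_force(a=1) * |r|`` over the muscles whose moment arm at
    this posture matches ``sign``; ignores the demands other DOFs place on
    bi-articular muscles, so it is an optimistic single-DOF capability.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    name = dof.name if isinstance(dof, DOF) else dof
    total = 0.0
    for m in model.muscles:
        if name not in m.spanned_dofs:
            continue
        r = moment_arm(m, name, float(angles[name]))
        if r * sign <= 0.0:
            continue
        state = muscle_kinematics(m, angles, angular_velocities)
        total += active_force(m, state, 1.0) * abs(r)
    return total


# ---------------------------------------------------------------------------
# Model definition files


def _model_from_dict(cfg: dict) -> MusculoskeletalModel:
    dofs = [
        DOF(name=d["name"], positive_direction_label=d.get("positive_direction_label", ""))
        for d in cfg["dofs"]
    ]
    muscles = [
        MuscleParams(
            name=m["name"],
            max_isometric_force=float(m["max_isometric_force"]),
            optimal_fiber_length=float(m["optimal_fiber_length"]),
            max_contraction_velocity=float(m.get("max_contraction_velocity", 10.0)),
            spanned_dofs=list(m["moment_arm_coeffs"].keys()),
            moment_arm_coeffs={k: list(map(float, v)) for k, v in m["moment_arm_coeffs"].items()},
            reference_fiber_length=(
                float(m["reference_fiber_length"]) if "reference_fiber_length" in m else None
            ),
        )
        for m in cfg["muscles"]
    ]
    segments = [
        SegmentProperties(
            name=s["name"],
            mass=float(s["mass"]),
            length=float(s["length"]),
            com=float(s["com"]),
            inertia=float(s["inertia"]),
        )
        for s in cfg["segments"]
    ]
    return MusculoskeletalModel(
        dofs=dofs,
        muscles=muscles,
        segment_properties=segments,
        body_mass=float(cfg["body_mass"]),
        name=cfg.get("name", "model"),
    )


def load_model(path) -> MusculoskeletalModel:
    """Load a model definition from a YAML file."""
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))


def planar9() -> MusculoskeletalModel:
    """The shipped default: planar sagittal lower limb, 3 DOFs, 9 muscle groups."""
    text = resources.files("capgap").joinpath("data/planar9.yaml").read_text()
    return _model_from_dict(yaml.safe_load(text))
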