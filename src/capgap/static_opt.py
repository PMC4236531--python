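"""Per-frame static optimization of the muscle-redundancy problem.

Each time frame poses a strictly convex quadratic program: minimize the
summed squared activations of the muscles and of ideal moment actuators
("reserves") subject to exact reproduction of the net joint moment at
every DOF,

    minimize   J = sum_t a_t^2 + sum_m a_m^2
    subject to tau_k = sum_t tau0_{t,k} a_t + sum_m gain_{m,k} a_m
               0 <= a_m <= 1,   a_t free,

where ``gain_{m,k} = F0_m f_L f_V r_{m,k}`` is the muscle's moment per
unit activation at the frame's posture and the reserve optimal moment
``tau0`` is small (1 Nm by default), making reserves costly: muscles are
preferred, and the reserve moment measures the capability gap.

Because each DOF has exactly one reserve with a free activation, the
equalities always have a solution.  Eliminating the reserves,
``a_t = (tau_k - sum_m gain a_m)/tau0_k``, turns the QP into a
bound-constrained linear least squares in the muscle activations alone,
which is solved exactly by an active-set method (BVLS).  The reserves are
then recovered from the equalities, so the moment constraint holds to
round-off by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .kinetics import TrialData
from .model import (
    MusculoskeletalModel,
    active_force,
    moment_arm,
    muscle_kinematics,
)

__all__ = [
    "ReserveActuator",
    "FrameProblem",
    "FrameSolution",
    "TrialSolution",
    "solve_frame",
    "solve_trial",
    "brute_force_oracle",
    "kkt_residual",
]

DEFAULT_RESERVE_OPTIMAL_MOMENT = 1.0  # Nm


@dataclass(frozen=True)
class ReserveActuator:
    """Ideal moment actuator at a DOF; moment = optimal_moment * activation."""

    dof: str
    optimal_moment: float = DEFAULT_RESERVE_OPTIMAL_MOMENT

    def __post_init__(self):
        if not self.optimal_moment > 0:
            raise ValueError("optimal_moment must be > 0")


@dataclass
class FrameProblem:
    """One frame's moment-matching problem.

    ``gains`` is (DOFs x muscles): Nm produced per unit activation of each
    muscle at each DOF (zero where the muscle does not span the DOF).
    One reserve per DOF, in DOF order.
    """

    required_moments: np.ndarray
    gains: np.ndarray
    reserves: Sequence[ReserveActuator]
    activation_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.required_moments = np.atleast_1d(np.asarray(self.required_moments, dtype=float))
        self.gains = np.atleast_2d(np.asarray(self.gains, dtype=float))
        k = self.required_moments.shape[0]
        if self.gains.shape[0] != k:
            raise ValueError(f"gains must have {k} rows (one per DOF)")
        if len(self.reserves) != k:
            raise ValueError("need exactly one reserve per DOF")
        if not np.all(np.isfinite(self.gains)) or not np.all(np.isfinite(self.required_moments)):
            raise ValueError("non-finite problem data")

    @property
    def n_dofs(self) -> int:
        return self.required_moments.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.gains.shape[1]

    @property
    def reserve_optimal_moments(self) -> np.ndarray:
        return np.array([r.optimal_moment for r in self.reserves])


@dataclass
class FrameSolution:
    """Activations minimizing the frame objective, with diagnostics."""

    muscle_activations: np.ndarray
    reserve_activations: np.ndarray
    objective_value: float
    moment_residual: np.ndarray
    solver_status: str  # "optimal" | "infeasible" | "max_iter"


def _objective(a_m: np.ndarray, a_t: np.ndarray) -> float:
    return float(np.dot(a_t, a_t) + np.dot(a_m, a_m))


def solve_frame(problem: FrameProblem) -> FrameSolution:
    """Global minimizer of the frame QP (unique: strictly convex objective)."""
    tau = problem.required_moments
    G = problem.gains
    tau0 = problem.reserve_optimal_moments
    lo, hi = problem.activation_bounds

    if problem.n_muscles == 0:
        a_t = tau / tau0
        return FrameSolution(
            muscle_activations=np.zeros(0),
            reserve_activations=a_t,
            objective_value=_objective(np.zeros(0), a_t),
            moment_residual=np.zeros_like(tau),
            solver_status="optimal",
        )

    # Reserve elimination: minimize |a_m|^2 + |(tau - G a_m)/tau0|^2 over bounds.
    C = np.vstack([G / tau0[:, None], np.eye(problem.n_muscles)])
    d = np.concatenate([tau / tau0, np.zeros(problem.n_muscles)])
    res = lsq_linear(C, d, bounds=(lo, hi), method="bvls", tol=1e-12)

    a_m = res.x
    a_t = (tau - G @ a_m) / tau0
    residual = G @ a_m + tau0 * a_t - tau
    status = "optimal" if res.status > 0 else "max_iter"
    return FrameSolution(
        muscle_activations=a_m,
        reserve_activations=a_t,
        objective_value=_objective(a_m, a_t),
        moment_residual=residual,
        solver_status=status,
    )


@dataclass
class TrialSolution:
    """Frame-by-frame solutions for one trial, in frame order."""

    time: np.ndarray
    muscle_names: Sequence[str]
    dof_names: Sequence[str]
    activations: np.ndarray  # frames x muscles
    reserve_activations: np.ndarray  # frames x DOFs
    reserve_optimal_moments: np.ndarray  # per DOF, Nm
    objective_values: np.ndarray
    statuses: Sequence[str] = field(default_factory=list)

    @property
    def reserve_moments(self) -> np.ndarray:
        """Per-frame reserve (capability-gap) moment, Nm, frames x DOFs."""
        return self.reserve_activations * self.reserve_optimal_moments[None, :]

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    def frame(self, i: int) -> FrameSolution:
        return FrameSolution(
            muscle_activations=self.activations[i],
            reserve_activations=self.reserve_activations[i],
            objective_value=float(self.objective_values[i]),
            moment_residual=np.zeros(len(self.dof_names)),
            solver_status=self.statuses[i] if self.statuses else "optimal",
        )


def build_frame_problem(
    model: MusculoskeletalModel,
    angles: dict[str, float],
    angular_velocities: dict[str, float],
    required_moments: np.ndarray,
    reserve_optimal_moment: float = DEFAULT_RESERVE_OPTIMAL_MOMENT,
) -> FrameProblem:
    """Assemble the gain matrix F0*fL*fV*r per muscle/DOF at one posture."""
    dof_names = model.dof_names
    gains = np.zeros((len(dof_names), len(model.muscles)))
    for m_idx, m in enumerate(model.muscles):
        state = muscle_kinematics(m, angles, angular_velocities)
        unit_force = active_force(m, state, 1.0)
        for dof_name in m.spanned_dofs:
            k = dof_names.index(dof_name)
            gains[k, m_idx] = unit_force * moment_arm(m, dof_name, angles[dof_name])
    reserves = [ReserveActuator(dof=d, optimal_moment=reserve_optimal_moment) for d in dof_names]
    return FrameProblem(required_moments=required_moments, gains=gains, reserves=reserves)


def solve_trial(
    model: MusculoskeletalModel,
    trial: TrialData,
    reserve_optimal_moment: float = DEFAULT_RESERVE_OPTIMAL_MOMENT,
) -> TrialSolution:
    """Solve every frame of a trial independently; deterministic.

    Frame-level solver failures are reported with the frame index.
    """
    if list(trial.dof_names) != model.dof_names:
        raise ValueError(
            f"trial DOFs {list(trial.dof_names)} do not match model DOFs {model.dof_names}"
        )
    n = trial.n_frames
    n_m = len(model.muscles)
    n_k = len(model.dof_names)
    activations = np.zeros((n, n_m))
    reserve_activations = np.zeros((n, n_k))
    objectives = np.zeros(n)
    statuses: list[str] = []
    for i in range(n):
        angles = dict(zip(trial.dof_names, trial.angles[i]))
        vels = dict(zip(trial.dof_names, trial.angular_velocities[i]))
        problem = build_frame_problem(
            model, angles, vels, trial.net_moments[i], reserve_optimal_moment
        )
        sol = solve_frame(problem)
        if sol.solver_status != "optimal":
            raise RuntimeError(f"frame {i}: solver status {sol.solver_status}")
        activations[i] = sol.muscle_activations
        reserve_activations[i] = sol.reserve_activations
        objectives[i] = sol.objective_value
        statuses.append(sol.solver_status)
    return TrialSolution(
        time=trial.time.copy(),
        muscle_names=[m.name for m in model.muscles],
        dof_names=list(model.dof_names),
        activations=activations,
        reserve_activations=reserve_activations,
        reserve_optimal_moments=np.full(n_k, reserve_optimal_moment),
        objective_values=objectives,
        statuses=statuses,
    )


def brute_force_oracle(problem: FrameProblem, grid_step: float = 1e-3) -> FrameSolution:
    """Grid-search reference for tiny instances (<= 3 muscles, <= 2 DOFs).

    Enumerates muscle activations on a grid; reserves follow exactly from
    the equality constraints at each grid point.  The returned objective
    is an upper bound on the QP optimum that converges as the step
    shrinks.  Independent of the QP solver.
    """
    if problem.n_muscles > 3 or problem.n_dofs > 2:
        raise ValueError("oracle restricted to <= 3 muscles and <= 2 DOFs")
    lo, hi = problem.activation_bounds
    axis = np.arange(lo, hi + grid_step / 2, grid_step)
    grids = np.meshgrid(*([axis] * problem.n_muscles), indexing="ij")
    A = np.stack([g.ravel() for g in grids], axis=0) if problem.n_muscles else np.zeros((0, 1))
    tau = problem.required_moments[:, None]
    tau0 = problem.reserve_optimal_moments[:, None]
    a_t = (tau - problem.gains @ A) / tau0
    J = np.sum(A**2, axis=0) + np.sum(a_t**2, axis=0)
    best = int(np.argmin(J))
    a_m = A[:, best]
    a_t_best = a_t[:, best]
    return FrameSolution(
        muscle_activations=a_m,
        reserve_activations=a_t_best,
        objective_value=float(J[best]),
        moment_residual=problem.gains @ a_m
        + problem.reserve_optimal_moments * a_t_best
        - problem.required_moments,
        solver_status="optimal",
    )


def kkt_residual(problem: FrameProblem, solution: FrameSolution, bound_tol: float = 1e-9) -> float:
    """Maximal stationarity violation of a candidate solution.

    Recovers the equality multipliers by least squares from the
    stationarity conditions of the free variables (all reserves, muscles
    strictly inside their bounds), then reports the largest violation of
    ``2a - A^T lambda`` with the sign conditions appropriate at active
    bounds.  Near zero certifies global optimality of the convex QP.
    """
    if solution.solver_status != "optimal":
        raise ValueError("kkt_residual requires an optimal-status solution")
    a_m = np.asarray(solution.muscle_activations, dtype=float)
    a_t = np.asarray(solution.reserve_activations, dtype=float)
    G = problem.gains
    tau0 = problem.reserve_optimal_moments
    lo, hi = problem.activation_bounds

    at_lower = a_m <= lo + bound_tol
    at_upper = a_m >= hi - bound_tol
    free = ~(at_lower | at_upper)

    # Stationarity rows: reserves 2 a_t = tau0 * lambda_k; free muscles
    # 2 a_m = (G^T lambda)_m.
    rows = [np.diag(tau0)]
    rhs = [2.0 * a_t]
    if np.any(free):
        rows.append(G[:, free].T)
        rhs.append(2.0 * a_m[free])
    A_ls = np.vstack(rows)
    b_ls = np.concatenate(rhs)
    lam, *_ = np.linalg.lstsq(A_ls, b_ls, rcond=None)

    s_m = 2.0 * a_m - G.T @ lam
    s_t = 2.0 * a_t - tau0 * lam
    viol = np.abs(s_t).tolist()
    viol += np.abs(s_m[free]).tolist()
    viol += np.maximum(0.0, s_m[at_upper]).tolist()  # need s <= 0 at upper bound
    viol += np.maximum(0.0, -s_m[at_lower]).tolist()  # need s >= 0 at lower bound
    return float(max(viol)) if viol else 0.0
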