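"""PID feedback dosing: error signals, discrete control law, closed-loop
simulation, and the combined optimal+PID sweep.

Two distinct pathways exist for the feedback signal u and both are kept:

* ``closed_loop_simulate`` treats u as a dosage *increment* computed online
  by the PID law from the tracking error history, applied as D + u at each
  step of the fractional solver;
* ``combined_optimal_pid_solve`` treats (u_I, u_T) as independently
  *optimized* controls alongside (D_I, D_T), with their own stationary
  points Psi scaled by the signal penalties c1, c2.

Setpoints: no published definition of the "desired state" exists; the
default policy tracks the tumor burden N toward 0 for the immunotherapy
error and the metastatic burden P toward 0 for the targeted-therapy error,
matching the therapies' stated targets.  Any component/reference pair is
configurable.

Base dosage D and signal u are clamped to [0, 1] *separately*, never their
sum: applied dosages D + u may legitimately reach 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .model import ModelParameters, InterventionStrengths, rhs_treated
from .pece import TimeGrid, Trajectory, predictor_weights, corrector_weights, _eval_rhs
from .control import (ObjectiveWeights, ControlSchedule, SweepResult, clamp01,
                      objective_J, control_update, _solve_forward, _solve_adjoint)

__all__ = [
    "PIDGains",
    "SetpointPolicy",
    "error_signals",
    "pid_signal",
    "closed_loop_simulate",
    "combined_optimal_pid_solve",
    "post_treatment_policy",
]

_STATE_INDEX = {"N": 0, "I": 1, "P": 2, "M": 3, "R": 4}


@dataclass(frozen=True)
class PIDGains:
    """Proportional, integral and derivative gains (shared by both loops).

    Defaults (0.5, 0.1, 0.05) are this package's documented choices; no
    published values exist.
    """

    K_p: float = 0.5
    K_i: float = 0.1
    K_d: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K_p", "K_i", "K_d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SetpointPolicy:
    """Maps each loop to a tracked state component and a reference level.

    Errors follow the convention e = actual - desired, so a state above its
    setpoint yields a positive error and hence positive dosing pressure.
    """

    immuno_component: str = "N"
    immuno_reference: float = 0.0
    targeted_component: str = "P"
    targeted_reference: float = 0.0

    def __post_init__(self) -> None:
        for comp in (self.immuno_component, self.targeted_component):
            if comp not in _STATE_INDEX:
                raise ValueError(f"unknown state component {comp!r}; options: {sorted(_STATE_INDEX)}")

    def as_dict(self) -> dict:
        return asdict(self)


def error_signals(states: np.ndarray, policy: SetpointPolicy) -> tuple[np.ndarray, np.ndarray]:
    """Tracking errors (e_I, e_T) = actual - desired along a state series."""
    y = np.atleast_2d(np.asarray(states, dtype=float))
    e_i = y[:, _STATE_INDEX[policy.immuno_component]] - policy.immuno_reference
    e_t = y[:, _STATE_INDEX[policy.targeted_component]] - policy.targeted_reference
    return e_i, e_t


def pid_signal(errors: np.ndarray, gains: PIDGains, grid: TimeGrid) -> np.ndarray:
    """Discrete PID law on an error series defined on the grid.

    u(t_j) = K_p e_j + K_i * (cumulative trapezoid of e up to t_j)
           + K_d * (e_j - e_{j-1})/h,  derivative term 0 at j = 0.

    Linear in the errors and in the gains; exact for constant errors
    (trapezoid is exact on constants).
    """
    e = np.asarray(errors, dtype=float)
    if e.shape[0] != len(grid):
        raise ValueError(f"error series has {e.shape[0]} samples but grid has {len(grid)} nodes")
    h = grid.step
    integral = np.concatenate([[0.0], np.cumsum((e[1:] + e[:-1]) * h / 2.0)])
    derivative = np.concatenate([[0.0], np.diff(e) / h])
    return gains.K_p * e + gains.K_i * integral + gains.K_d * derivative


def _pid_terms(e_hist: np.ndarray, h: float, gains: PIDGains) -> float:
    """PID output at the newest node of an error history (trapezoid integral)."""
    e = e_hist
    integral = float(np.trapezoid(e, dx=h)) if e.size > 1 else 0.0
    derivative = (e[-1] - e[-2]) / h if e.size > 1 else 0.0
    return gains.K_p * e[-1] + gains.K_i * integral + gains.K_d * derivative


def closed_loop_simulate(order: float, grid: TimeGrid, y0,
                         params: ModelParameters, strengths: InterventionStrengths,
                         gains: PIDGains, policy: SetpointPolicy,
                         base_dosages: tuple[float, float] = (0.0, 0.0),
                         t_off: float | None = None):
    """Step the fractional system with dosages D + u recomputed each step.

    The PID signal at node j is computed causally from the error history up
    to j (errors at the newest node are first taken from the predicted
    state, then refreshed from the corrected state).  Base dosages and
    signals are each clamped to [0, 1]; the applied sum may reach 2.
    ``t_off`` switches the feedback off for t > t_off (post-treatment
    monitoring); by default the horizon itself, i.e. feedback active on the
    whole run.

    Returns ``(Trajectory, ControlSchedule)`` where the schedule carries the
    applied D, u and the error series.
    """
    h = grid.step
    ts = grid.nodes
    n_nodes = len(grid)
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    d_i0, d_t0 = clamp01(base_dosages[0]), clamp01(base_dosages[1])
    if t_off is None:
        t_off = grid.t_final

    y = np.empty((n_nodes, 5))
    y[0] = y0
    u_I = np.zeros(n_nodes)
    u_T = np.zeros(n_nodes)
    e_I = np.zeros(n_nodes)
    e_T = np.zeros(n_nodes)
    f_corr = np.empty((n_nodes, 5))
    f_pred = np.empty((n_nodes, 5))

    def applied_rhs(j, state, node):
        return _eval_rhs(
            lambda t, s: rhs_treated(s, params, strengths,
                                     (d_i0 + u_I[j], d_t0 + u_T[j])),
            ts[j], state, node)

    e_I[0], e_T[0] = (v[0] for v in error_signals(y0[None, :], policy))
    if post_treatment_policy(ts[0], t_off):
        u_I[0] = float(clamp01(_pid_terms(e_I[:1], h, gains)))
        u_T[0] = float(clamp01(_pid_terms(e_T[:1], h, gains)))
    f_corr[0] = applied_rhs(0, y0, 0)

    pre = h ** order / math.gamma(order + 1.0)
    cor = h ** order / math.gamma(order + 2.0)

    for n in range(grid.n_steps):
        b = predictor_weights(n, order)
        y_pred = y0 + pre * (b[:, None] * f_corr[: n + 1]).sum(axis=0)
        # provisional feedback at the new node from the predicted state
        ei_p, et_p = (v[0] for v in error_signals(y_pred[None, :], policy))
        e_I[n + 1], e_T[n + 1] = ei_p, et_p
        if post_treatment_policy(ts[n + 1], t_off):
            u_I[n + 1] = float(clamp01(_pid_terms(e_I[: n + 2], h, gains)))
            u_T[n + 1] = float(clamp01(_pid_terms(e_T[: n + 2], h, gains)))
        else:
            u_I[n + 1] = u_T[n + 1] = 0.0
        f_pred[n + 1] = applied_rhs(n + 1, y_pred, n + 1)
        a_new, a_old = corrector_weights(n, order)
        y[n + 1] = y0 + cor * (
            (a_new[:, None] * f_pred[1 : n + 2]).sum(axis=0)
            + (a_old[:, None] * f_corr[: n + 1]).sum(axis=0)
        )
        # refresh error/signal at the corrected state before it enters history
        ei_c, et_c = (v[0] for v in error_signals(y[n + 1][None, :], policy))
        e_I[n + 1], e_T[n + 1] = ei_c, et_c
        if post_treatment_policy(ts[n + 1], t_off):
            u_I[n + 1] = float(clamp01(_pid_terms(e_I[: n + 2], h, gains)))
            u_T[n + 1] = float(clamp01(_pid_terms(e_T[: n + 2], h, gains)))
        f_corr[n + 1] = applied_rhs(n + 1, y[n + 1], n + 1)

    traj = Trajectory(grid=grid, values=y,
                      meta={"order": order, "step": h, "scheme": "pece-closed-loop",
                            "gains": gains.as_dict(), "policy": policy.as_dict()})
    sched = ControlSchedule(grid, np.full(n_nodes, d_i0), np.full(n_nodes, d_t0),
                            u_I=u_I, u_T=u_T)
    sched.e_I = e_I
    sched.e_T = e_T
    return traj, sched


def post_treatment_policy(t: float, horizon: float) -> bool:
    """Feedback-active flag: PID law applies for t <= horizon, off afterwards."""
    return t <= horizon


def combined_optimal_pid_solve(order, grid: TimeGrid, y0, params: ModelParameters,
                               strengths: InterventionStrengths,
                               weights: ObjectiveWeights,
                               *, tol: float = 1e-6, max_iter: int = 200,
                               relaxation: float = 0.5,
                               adjoint_stepper: str = "fractional") -> SweepResult:
    """Forward-backward sweep with four clamped controls D_I*, D_T*, u_I*, u_T*.

    The signal stationary points Psi differ from the dosage ones Delta only
    through the penalties (c vs b); as c grows the optimal signals vanish
    and the problem reduces to the plain optimal-dosing sweep.
    """
    if weights.c1 <= 0 or weights.c2 <= 0:
        raise ValueError("combined sweep requires strictly positive c1, c2")
    n_nodes = len(grid)
    D_I = np.zeros(n_nodes)
    D_T = np.zeros(n_nodes)
    u_I = np.zeros(n_nodes)
    u_T = np.zeros(n_nodes)
    J_history: list[float] = []
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        states = _solve_forward(order, grid, y0, params, strengths, D_I, D_T, u_I, u_T)
        adjoints = _solve_adjoint(order, grid, states, params, strengths, weights,
                                  D_I, D_T, variant="pid", u_I=u_I, u_T=u_T,
                                  stepper=adjoint_stepper)
        new = np.empty((n_nodes, 4))
        for j in range(n_nodes):
            (_, _, ci, ct, _, _, ui, ut) = control_update(
                states.values[j], adjoints[j], strengths, weights, variant="pid")
            new[j] = (ci, ct, ui, ut)
        old = np.column_stack([D_I, D_T, u_I, u_T])
        upd = (1.0 - relaxation) * old + relaxation * new
        change = np.abs(upd - old).max()
        D_I, D_T, u_I, u_T = upd.T.copy()
        sched = ControlSchedule(grid, D_I, D_T, u_I=u_I, u_T=u_T)
        J_history.append(objective_J(states, sched, weights))
        if change < tol:
            converged = True
            break

    states = _solve_forward(order, grid, y0, params, strengths, D_I, D_T, u_I, u_T)
    adjoints = _solve_adjoint(order, grid, states, params, strengths, weights,
                              D_I, D_T, variant="pid", u_I=u_I, u_T=u_T,
                              stepper=adjoint_stepper)
    sched = ControlSchedule(grid, D_I, D_T, u_I=u_I, u_T=u_T)
    J_final = objective_J(states, sched, weights)
    from .control import _stationarity
    stat = _stationarity(states, adjoints, D_I, D_T, strengths, weights)
    return SweepResult(sched, states, adjoints, J_final, J_history,
                       iterations, converged, stat)
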