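"""Periodic-orbit solving: simulation, single shooting, steady-state detection.

The periodic boundary-value problem x(T; x0) = x0 is solved by Newton
iteration on a single-shooting residual, with the Jacobian assembled from
the monodromy matrix (fundamental solution of the variational equations
over one period).  The time-translation degeneracy is removed by a phase
condition anchoring the orbit at a maximum of the first state:
f_1(x0, p) = 0 with d²x1/dt² < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .data import TimeSeriesDataset
from .errors import (
    ArgumentError,
    IntegrationError,
    NoCycleError,
    SteadyStateError,
)
from .model import OscillatorModel, Trajectory

__all__ = [
    "LimitCycle",
    "simulate",
    "find_limit_cycle",
    "detect_steady_state",
    "estimate_period",
]

#: default integrator tolerances (relative, absolute)
RTOL = 1e-8
ATOL = 1e-10
#: relative peak-to-peak amplitude below which an orbit counts as steady state
STEADY_THRESHOLD = 1e-3


@dataclass
class LimitCycle:
    """A periodic orbit: period, anchor point and dense one-period trajectory.

    ``anchor_state`` lies on the orbit at a maximum of the first state
    (the phase convention used throughout the package).  ``sampler`` maps
    any time to the state on the orbit, wrapping modulo the period.
    """

    period: float
    anchor_state: np.ndarray
    params: np.ndarray
    amplitude: np.ndarray          # per-state peak-to-peak range
    residual: float                # periodicity residual of the shooting solve
    _dense: Callable = field(repr=False, default=None)

    def sampler(self, t) -> np.ndarray:
        """State on the orbit at time(s) ``t`` (t=0 is the anchor)."""
        t = np.mod(np.asarray(t, dtype=float), self.period)
        return self._dense(t)

    def sample(self, times) -> Trajectory:
        times = np.asarray(times, dtype=float)
        return Trajectory(times=times, values=self.sampler(times))


def simulate(
    model: OscillatorModel,
    p: np.ndarray,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``times`` (stiff-capable initial-value solve)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ArgumentError("times must be 1-d and strictly increasing")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ArgumentError("parameters must be positive")
    x0 = np.asarray(x0, dtype=float)
    jac = (lambda t, x: model.fx(x, p)) if model.jac_x is not None else None
    sol = solve_ivp(
        lambda t, x: model.rhs(x, p),
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if sol.t.size else times[0]:.6g}: "
            f"{sol.message}",
            time=float(sol.t[-1]) if sol.t.size else float(times[0]),
        )
    return Trajectory(times=sol.t, values=sol.y)


def _flow(model, p, x0, t_span, *, rtol=RTOL, atol=ATOL, dense=False, events=None,
          t_eval=None):
    """Low-level solve_ivp wrapper returning the raw solution object."""
    jac = (lambda t, x: model.fx(x, p)) if model.jac_x is not None else None
    sol = solve_ivp(
        lambda t, x: model.rhs(x, p),
        t_span,
        np.asarray(x0, float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=jac,
        dense_output=dense,
        events=events,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}",
                               time=float(sol.t[-1]) if sol.t.size else None)
    return sol


def _flow_with_monodromy(model, p, x0, T, rtol=RTOL, atol=ATOL):
    """Integrate state + variational equations over [0, T].

    Returns (x(T), monodromy matrix dx(T)/dx0).
    """
    neq = model.neq
    y0 = np.concatenate([x0, np.eye(neq).ravel()])

    def rhs(t, y):
        x = y[:neq]
        phi = y[neq:].reshape(neq, neq)
        jx = model.fx(x, p)
        return np.concatenate([model.f(x, p), (jx @ phi).ravel()])

    sol = solve_ivp(rhs, (0.0, T), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"variational integration failed: {sol.message}")
    yT = sol.y[:, -1]
    return yT[:neq], yT[neq:].reshape(neq, neq)


def _newton_polish(
    model: OscillatorModel,
    p: np.ndarray,
    x0: np.ndarray,
    T: float,
    tol: float = 1e-8,
    max_iter: int = 50,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[np.ndarray, float, float, int]:
    """Newton on the shooting residual [x(T;x0) - x0; f1(x0,p)].

    Returns (x0, T, residual_norm, n_iterations).  Raises NoCycleError on
    non-convergence.  Assumes the guess is already near an x1-maximum.
    """
    x0 = np.asarray(x0, dtype=float).copy()
    T = float(T)
    neq = model.neq
    res_norm = np.inf
    for it in range(max_iter):
        xT, mono = _flow_with_monodromy(model, p, x0, T, rtol=rtol, atol=atol)
        fx0 = model.f(x0, p)
        res = np.concatenate([xT - x0, [fx0[0]]])
        res_norm = float(np.linalg.norm(res))
        if res_norm <= tol * (1.0 + float(np.linalg.norm(x0))):
            return x0, T, res_norm, it
        jac = np.zeros((neq + 1, neq + 1))
        jac[:neq, :neq] = mono - np.eye(neq)
        jac[:neq, neq] = model.f(xT, p)
        jac[neq, :neq] = model.fx(x0, p)[0]
        try:
            step = np.linalg.solve(jac, -res)
        except np.linalg.LinAlgError as exc:
            raise NoCycleError(f"singular shooting Jacobian: {exc}") from exc
        # damped update: halve until the residual decreases (or give up damping)
        lam = 1.0
        for _ in range(6):
            x_new = x0 + lam * step[:neq]
            T_new = T + lam * step[neq]
            if T_new <= 0:
                lam *= 0.5
                continue
            xT_new = _flow(model, p, x_new, (0.0, T_new), rtol=rtol, atol=atol).y[:, -1]
            res_new = np.concatenate([xT_new - x_new, [model.f(x_new, p)[0]]])
            if np.linalg.norm(res_new) < res_norm:
                break
            lam *= 0.5
        x0 = x0 + lam * step[:neq]
        T = T + lam * step[neq]
        if T <= 0:
            raise NoCycleError("Newton iteration drove the period non-positive")
    raise NoCycleError(
        f"shooting Newton did not converge in {max_iter} iterations "
        f"(residual {res_norm:.3e})"
    )


def _build_cycle(model, p, x0, T, residual, steady_threshold) -> LimitCycle:
    sol = _flow(model, p, x0, (0.0, T), dense=True)
    grid = np.linspace(0.0, T, 513)
    vals = sol.sol(grid)
    amplitude = vals.max(axis=1) - vals.min(axis=1)
    scale = np.maximum(np.abs(vals).mean(axis=1), 1e-12)
    if np.max(amplitude / scale) < steady_threshold:
        raise SteadyStateError(
            "converged orbit has negligible amplitude (steady state)"
        )
    dense = sol.sol
    return LimitCycle(
        period=float(T),
        anchor_state=np.asarray(x0, float).copy(),
        params=np.asarray(p, float).copy(),
        amplitude=amplitude,
        residual=float(residual),
        _dense=dense,
    )


def find_limit_cycle(
    model: OscillatorModel,
    p: np.ndarray,
    x0_guess: np.ndarray,
    T_guess: float,
    tol: float = 1e-8,
    max_iter: int = 50,
    steady_threshold: float = STEADY_THRESHOLD,
    transient_periods: float = 10.0,
    min_period_fraction: float = 1e-3,
) -> LimitCycle:
    """Find the limit cycle near ``x0_guess`` with period near ``T_guess``.

    Strategy: integrate through the transient, anchor the guess at a maximum
    of the first state (phase condition), refine period guess from successive
    maxima, then polish with Newton on the shooting residual.  The returned
    period is checked to be fundamental (the half-period map does not fix the
    anchor).

    Raises
    ------
    SteadyStateError
        if the trajectory relaxes to a fixed point or the converged orbit
        has negligible amplitude.
    NoCycleError
        if the Newton iteration fails to converge.
    """
    if T_guess <= 0:
        raise ArgumentError("T_guess must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ArgumentError("parameters must be positive")

    # -- transient + anchor location via x1-maximum events -----------------
    t_end = transient_periods * T_guess

    def x1_max_event(t, x):
        return model.rhs(x, p)[0]

    x1_max_event.direction = -1.0
    sol = _flow(model, p, x0_guess, (0.0, t_end), dense=True, events=[x1_max_event])
    events = sol.t_events[0]
    # keep events in the settled part of the run (last ~40%)
    late = events[events > 0.6 * t_end]

    tail = np.linspace(max(0.0, t_end - 2 * T_guess), t_end, 400)
    tail_vals = sol.sol(tail)
    amp = tail_vals.max(axis=1) - tail_vals.min(axis=1)
    scale = np.maximum(np.abs(tail_vals).mean(axis=1), 1e-12)
    if np.max(amp / scale) < steady_threshold:
        raise SteadyStateError("trajectory relaxed to a fixed point")

    if late.size >= 2:
        T0 = float(np.diff(late[-4:]).mean()) if late.size >= 2 else T_guess
        anchor = sol.sol(late[-1])
    elif events.size >= 2:
        T0 = float(np.diff(events[-2:]).mean())
        anchor = sol.sol(events[-1])
    else:
        raise NoCycleError("no x1 maxima found during pre-integration")

    x0, T, residual, _ = _newton_polish(model, p, anchor, T0, tol=tol, max_iter=max_iter)

    # fundamental-period check: the half-period map must not fix the anchor
    min_period = min_period_fraction * T_guess
    while T / 2.0 > min_period:
        x_half = _flow(model, p, x0, (0.0, T / 2.0)).y[:, -1]
        if np.linalg.norm(x_half - x0) > 100 * tol * (1.0 + np.linalg.norm(x0)):
            break
        T = T / 2.0
        x0, T, residual, _ = _newton_polish(model, p, x0, T, tol=tol, max_iter=max_iter)

    return _build_cycle(model, p, x0, T, residual, steady_threshold)


def refine_limit_cycle(
    model: OscillatorModel,
    p: np.ndarray,
    x0: np.ndarray,
    T: float,
    tol: float = 1e-8,
    max_iter: int = 50,
    steady_threshold: float = STEADY_THRESHOLD,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> LimitCycle:
    """Warm-started polish: Newton directly from (x0, T) without transient.

    ``x0`` need not be exactly at the phase anchor; a short integration
    locates the nearest x1-maximum first.  Used for re-solving after a
    collocation fit and inside finite-difference sensitivity loops.
    """
    p = np.asarray(p, dtype=float)

    def x1_max_event(t, x):
        return model.rhs(x, p)[0]

    x1_max_event.direction = -1.0
    sol = _flow(model, p, x0, (0.0, 1.5 * T), dense=True, events=[x1_max_event],
                rtol=rtol, atol=atol)
    events = sol.t_events[0]
    anchor = sol.sol(events[0]) if events.size else np.asarray(x0, float)
    x0_new, T_new, residual, _ = _newton_polish(
        model, p, anchor, T, tol=tol, max_iter=max_iter, rtol=rtol, atol=atol
    )
    return _build_cycle(model, p, x0_new, T_new, residual, steady_threshold)


def detect_steady_state(
    traj: Trajectory,
    threshold: float = STEADY_THRESHOLD,
    period: float | None = None,
) -> bool:
    """True iff every state is flat over the final period of the trajectory.

    "Flat" means peak-to-peak range below ``threshold`` times the state's
    mean magnitude (with an absolute floor for states hovering near zero).
    ``period`` defaults to half the trajectory span; the trajectory must
    cover at least two periods.
    """
    if period is None:
        period = traj.span / 2.0
    if traj.span < 2.0 * period:
        raise ArgumentError(
            f"trajectory span {traj.span:.3g} covers less than two periods "
            f"({period:.3g} each)"
        )
    window = traj.times >= traj.times[-1] - period
    vals = traj.values[:, window]
    amp = vals.max(axis=1) - vals.min(axis=1)
    scale = np.maximum(np.abs(vals).mean(axis=1), 1e-12)
    return bool(np.all(amp / scale < threshold))


def estimate_period(
    dataset: TimeSeriesDataset, flat_threshold: float = 0.01
) -> float:
    """Period guess from data assumed to sample exactly one cycle.

    With M points equispaced over one period [0, T), the grid span plus one
    sampling interval recovers T.  Raises on flat (non-oscillatory) data.
    """
    if dataset.n_samples < 4:
        raise ArgumentError("need at least 4 sampling points to estimate a period")
    means = np.ma.masked_invalid(dataset.means)
    amp = (means.max(axis=1) - means.min(axis=1)).filled(0.0)
    scale = np.maximum(np.abs(means).mean(axis=1).filled(0.0), 1e-12)
    if np.max(amp / scale) < flat_threshold:
        raise ArgumentError("data look flat: cannot estimate an oscillation period")
    dt = float(np.median(np.diff(dataset.times)))
    return float(dataset.times[-1] - dataset.times[0]) + dt
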