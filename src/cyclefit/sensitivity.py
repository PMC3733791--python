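"""Relative period sensitivities d(lnT)/d(lnp) of a limit cycle.

The primary route differentiates the periodic shooting residual.  Writing
phi(T, x0, p) for the flow map and g(x0, p) = f_1(x0, p) for the phase
condition (anchor at a maximum of state 1), the orbit satisfies

    phi(T, x0, p) - x0 = 0,    g(x0, p) = 0.

Differentiating with respect to p gives the bordered linear system

    [ M - I   f(x0) ] [ dx0/dp ]     [ S_p      ]
    [ dg/dx     0   ] [ dT/dp  ]  = -[ dg/dp    ]

where M is the monodromy matrix (dphi/dx0 over one period) and S_p the
parametric trajectory sensitivities dphi/dp at fixed x0, both obtained by
integrating the variational equations alongside the state.  The relative
sensitivity is then s_k = (p_k / T) dT/dp_k.  An independent
central-finite-difference oracle re-solves the orbit at perturbed
parameters; the two routes are required to agree in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ArgumentError,
    DegeneracyError,
    IntegrationError,
    NoCycleError,
    SteadyStateError,
)
from .limit_cycle import LimitCycle, refine_limit_cycle
from .model import OscillatorModel

__all__ = [
    "PeriodSensitivity",
    "variational_period_sensitivities",
    "fd_period_sensitivities",
    "finite_ratio_sensitivity",
]


@dataclass
class PeriodSensitivity:
    """Relative period sensitivities (p_k/T) dT/dp_k, dimensionless.

    ``values`` entries are NaN where the sensitivity is undefined (e.g. a
    finite-difference perturbation destroyed the oscillation); the
    ``undefined`` mask marks those entries.
    """

    values: np.ndarray
    method: str                     # "variational" | "finite_difference"
    param_names: Sequence[str] | None = None
    condition_number: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def undefined(self) -> np.ndarray:
        return np.isnan(self.values)


def variational_period_sensitivities(
    model: OscillatorModel,
    cycle: LimitCycle,
    p: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    cond_limit: float = 1e10,
) -> PeriodSensitivity:
    """Period sensitivities from the bordered shooting-residual system."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ArgumentError("parameters must be positive")
    neq, npar = model.neq, model.nparams
    x0 = cycle.anchor_state
    T = cycle.period

    def rhs(t, y):
        x = y[:neq]
        phi = y[neq : neq + neq * neq].reshape(neq, neq)
        s = y[neq + neq * neq :].reshape(neq, npar)
        jx = model.fx(x, p)
        return np.concatenate([
            model.f(x, p),
            (jx @ phi).ravel(),
            (jx @ s + model.fp(x, p)).ravel(),
        ])

    y0 = np.concatenate([x0, np.eye(neq).ravel(), np.zeros(neq * npar)])
    sol = solve_ivp(rhs, (0.0, T), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"variational integration failed: {sol.message}")
    yT = sol.y[:, -1]
    xT = yT[:neq]
    mono = yT[neq : neq + neq * neq].reshape(neq, neq)
    s_p = yT[neq + neq * neq :].reshape(neq, npar)

    bordered = np.zeros((neq + 1, neq + 1))
    bordered[:neq, :neq] = mono - np.eye(neq)
    bordered[:neq, neq] = model.f(xT, p)
    bordered[neq, :neq] = model.fx(x0, p)[0]
    rhs_mat = np.zeros((neq + 1, npar))
    rhs_mat[:neq] = -s_p
    rhs_mat[neq] = -model.fp(x0, p)[0]

    cond = float(np.linalg.cond(bordered))
    if not np.isfinite(cond) or cond > cond_limit:
        raise DegeneracyError(
            f"bordered sensitivity system is near-singular (cond={cond:.3e}); "
            "the orbit may be degenerate"
        )
    solution = np.linalg.solve(bordered, rhs_mat)
    dT_dp = solution[neq]
    values = p / T * dT_dp
    return PeriodSensitivity(
        values=values,
        method="variational",
        param_names=list(model.param_names),
        condition_number=cond,
    )


def fd_period_sensitivities(
    model: OscillatorModel,
    cycle: LimitCycle,
    p: np.ndarray,
    rel_step: float = 1e-3,
) -> PeriodSensitivity:
    """Central-difference oracle: (lnT+ - lnT-) / (2*rel_step) per parameter.

    Each perturbed orbit is re-solved warm-started from the unperturbed one.
    Parameters whose perturbation destroys the oscillation are flagged
    undefined (NaN).
    """
    if not 0.0 < rel_step <= 0.1:
        raise ArgumentError("rel_step must lie in (0, 0.1]")
    p = np.asarray(p, dtype=float)
    values = np.empty(model.nparams)
    for k in range(model.nparams):
        log_periods = []
        for sign in (+1.0, -1.0):
            p_pert = p.copy()
            p_pert[k] = p[k] * (1.0 + sign * rel_step)
            try:
                pert = refine_limit_cycle(
                    model, p_pert, cycle.anchor_state, cycle.period,
                    tol=1e-10, rtol=1e-11, atol=1e-13,
                )
            except (SteadyStateError, NoCycleError, IntegrationError):
                log_periods = None
                break
            log_periods.append(np.log(pert.period))
        values[k] = (
            (log_periods[0] - log_periods[1]) / (2.0 * rel_step)
            if log_periods is not None
            else np.nan
        )
    return PeriodSensitivity(
        values=values,
        method="finite_difference",
        param_names=list(model.param_names),
    )


def finite_ratio_sensitivity(
    period_change_fraction: float, param_change_fraction: float
) -> float:
    """Finite-ratio sensitivity: fractional period change per fractional
    parameter change.

    Calibrates which relative period sensitivities are experimentally
    measurable: e.g. a 5% period change caused by a 50% rate increase
    corresponds to a magnitude of 0.1.
    """
    if param_change_fraction == 0:
        raise ArgumentError("parameter change fraction must be nonzero")
    return period_change_fraction / param_change_fraction
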