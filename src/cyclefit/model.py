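"""Autonomous ODE oscillator models and built-in fixtures.

An :class:`OscillatorModel` bundles an autonomous right-hand side
``dx/dt = f(x, p)`` with state/parameter names and a nominal parameter
vector.  The package ships a Goodwin-type negative-feedback loop as its
reference oscillator: a three-stage cascade (mRNA -> cytosolic protein ->
nuclear repressor) in which the end product represses transcription through
a steep Hill function.  Sustained oscillations require high cooperativity
(Hill exponent around 8 or above for comparable degradation rates), which is
why the fixture uses n = 10 and the damped control uses n = 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ArgumentError, EvaluationError

__all__ = [
    "OscillatorModel",
    "Trajectory",
    "evaluate_rhs",
    "goodwin_fixture",
    "damped_fixture",
    "MODEL_REGISTRY",
    "model_from_config",
    "load_model",
]


@dataclass
class OscillatorModel:
    """Autonomous ODE model ``dx/dt = f(x, p)`` with named states/parameters.

    Parameters are kinetic rate constants and are constrained positive
    throughout the package.  ``jac_x`` / ``jac_p`` are optional analytic
    Jacobians; when absent, central finite differences are used (the
    variational and collocation machinery needs both).
    """

    state_names: Sequence[str]
    param_names: Sequence[str]
    rhs: Callable[[np.ndarray, np.ndarray], np.ndarray]
    nominal_params: np.ndarray
    period_hint: float | None = None
    jac_x: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    jac_p: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.state_names = list(self.state_names)
        self.param_names = list(self.param_names)
        if len(set(self.state_names)) != len(self.state_names):
            raise ArgumentError("state_names must be unique")
        if len(set(self.param_names)) != len(self.param_names):
            raise ArgumentError("param_names must be unique")
        self.nominal_params = np.asarray(self.nominal_params, dtype=float)
        if self.nominal_params.shape != (len(self.param_names),):
            raise ArgumentError(
                f"nominal_params has shape {self.nominal_params.shape}, "
                f"expected ({len(self.param_names)},)"
            )
        if not np.all(np.isfinite(self.nominal_params)):
            raise ArgumentError("nominal_params must be finite")
        if np.any(self.nominal_params <= 0):
            raise ArgumentError("nominal_params must be positive rate constants")
        if self.period_hint is not None and self.period_hint <= 0:
            raise ArgumentError("period_hint must be positive")

    @property
    def neq(self) -> int:
        return len(self.state_names)

    @property
    def nparams(self) -> int:
        return len(self.param_names)

    # -- derivative evaluation -------------------------------------------
    def f(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return evaluate_rhs(self, x, p)

    def fx(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """State Jacobian df/dx, analytic if available else central FD."""
        if self.jac_x is not None:
            return np.asarray(self.jac_x(np.asarray(x, float), np.asarray(p, float)), float)
        return _fd_jacobian(lambda v: self.f(v, p), np.asarray(x, float), self.neq)

    def fp(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Parameter Jacobian df/dp, analytic if available else central FD."""
        if self.jac_p is not None:
            return np.asarray(self.jac_p(np.asarray(x, float), np.asarray(p, float)), float)
        return _fd_jacobian(lambda v: self.f(x, v), np.asarray(p, float), self.neq)


def _fd_jacobian(fun: Callable[[np.ndarray], np.ndarray], v: np.ndarray, nrows: int) -> np.ndarray:
    jac = np.empty((nrows, v.size))
    for k in range(v.size):
        step = 1e-7 * max(abs(v[k]), 1.0)
        vp = v.copy()
        vm = v.copy()
        vp[k] += step
        vm[k] -= step
        jac[:, k] = (fun(vp) - fun(vm)) / (2.0 * step)
    return jac


def evaluate_rhs(model: OscillatorModel, x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Evaluate ``f(x, p)`` with dimension and finiteness checks."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != (model.neq,):
        raise ArgumentError(f"state vector has shape {x.shape}, expected ({model.neq},)")
    if p.shape != (model.nparams,):
        raise ArgumentError(f"parameter vector has shape {p.shape}, expected ({model.nparams},)")
    out = np.asarray(model.rhs(x, p), dtype=float)
    if out.shape != (model.neq,):
        raise ArgumentError(
            f"rhs returned shape {out.shape}, expected ({model.neq},)"
        )
    if not np.all(np.isfinite(out)):
        raise EvaluationError(f"rhs returned non-finite values at x={x!r}")
    return out


@dataclass
class Trajectory:
    """Discrete representation of a solution x(t) on a time grid."""

    times: np.ndarray
    values: np.ndarray  # shape (NEQ, len(times))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise ArgumentError("times must be a 1-d grid with at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ArgumentError("times must be strictly increasing")
        if self.values.shape[1] != self.times.size:
            raise ArgumentError(
                f"values shape {self.values.shape} incompatible with {self.times.size} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("trajectory values must be finite")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------

#: Nominal rates for the oscillatory Goodwin fixture.  With Hill exponent 10
#: these give a stable limit cycle of period ~19.81 time units with
#: peak-to-peak amplitudes of roughly 0.17 / 0.40 / 1.05 in the three states.
GOODWIN_NOMINAL = np.array([4.0, 0.2, 1.0, 0.2, 1.0, 0.2])
GOODWIN_PERIOD_HINT = 19.81


def goodwin_fixture(hill_exponent: float = 10.0) -> OscillatorModel:
    """Three-state Goodwin negative-feedback oscillator.

    dx1/dt = a / (1 + x3**n) - b*x1
    dx2/dt = c*x1 - d*x2
    dx3/dt = e*x2 - g*x3

    The Hill exponent ``n`` is a structural constant, not an estimated
    parameter.  At the default ``n = 10`` the nominal rates sustain a limit
    cycle; lowering ``n`` below the cooperativity threshold (e.g. 2) makes
    the fixed point stable, which is useful as a negative control.
    """
    n = float(hill_exponent)

    def rhs(x, p):
        a, b, c, d, e, g = p
        hill = a / (1.0 + x[2] ** n)
        return np.array([
            hill - b * x[0],
            c * x[0] - d * x[1],
            e * x[1] - g * x[2],
        ])

    def jac_x(x, p):
        a, b, c, d, e, g = p
        xn = x[2] ** n
        dhill = -a * n * x[2] ** (n - 1.0) / (1.0 + xn) ** 2
        return np.array([
            [-b, 0.0, dhill],
            [c, -d, 0.0],
            [0.0, e, -g],
        ])

    def jac_p(x, p):
        xn = x[2] ** n
        return np.array([
            [1.0 / (1.0 + xn), -x[0], 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, x[0], -x[1], 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, x[1], -x[2]],
        ])

    return OscillatorModel(
        state_names=["x1", "x2", "x3"],
        param_names=["a", "b", "c", "d", "e", "g"],
        rhs=rhs,
        nominal_params=GOODWIN_NOMINAL.copy(),
        period_hint=GOODWIN_PERIOD_HINT if n >= 8 else None,
        jac_x=jac_x,
        jac_p=jac_p,
        name=f"goodwin(n={n:g})",
    )


def damped_fixture() -> OscillatorModel:
    """Goodwin loop below the oscillation threshold (Hill exponent 2).

    Its nominal parameters yield a globally attracting fixed point, so every
    trajectory is a damped oscillation.  Used as the negative control for
    steady-state detection and bootstrap trial discarding.
    """
    m = goodwin_fixture(hill_exponent=2.0)
    m.nominal_params = np.array([1.0, 0.1, 1.0, 0.1, 1.0, 0.1])
    # characteristic relaxation time, used to size simulation windows
    m.period_hint = 40.0
    m.name = "goodwin-damped(n=2)"
    return m


MODEL_REGISTRY: dict[str, Callable[[], OscillatorModel]] = {
    "goodwin": goodwin_fixture,
    "goodwin_damped": damped_fixture,
}


def model_from_config(config: Mapping) -> OscillatorModel:
    """Build a model from a config mapping.

    Keys: ``model`` (registry key selecting a built-in rhs), optional
    ``params`` (mapping name -> value overriding nominal values) and
    ``period_hint``.  User-defined right-hand sides are supplied
    programmatically, not through config files.
    """
    try:
        key = config["model"]
    except KeyError:
        raise ArgumentError("model config requires a 'model' registry key") from None
    try:
        factory = MODEL_REGISTRY[key]
    except KeyError:
        raise ArgumentError(
            f"unknown model {key!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    model = factory()
    overrides = config.get("params")
    if overrides:
        p = model.nominal_params.copy()
        for pname, value in overrides.items():
            if pname not in model.param_names:
                raise ArgumentError(f"unknown parameter {pname!r} for model {key!r}")
            p[model.param_names.index(pname)] = float(value)
        if np.any(p <= 0):
            raise ArgumentError("parameter overrides must be positive")
        model.nominal_params = p
    if "period_hint" in config and config["period_hint"] is not None:
        model.period_hint = float(config["period_hint"])
    return model


def load_model(path: str | Path) -> OscillatorModel:
    """Load a model config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ArgumentError(f"model config {path} must be a mapping")
    return model_from_config(config)
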