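"""Exception hierarchy for cyclefit.

Argument/validation problems raise :class:`ArgumentError` (a ``ValueError``)
so they also behave idiomatically for callers using plain ``except ValueError``.
Numerical failures (integration blow-up, Newton non-convergence, degenerate
orbits) have dedicated classes because the bootstrap engine dispatches on
them to decide whether a trial is discarded as *failed* or as *steady state*.
"""

from __future__ import annotations


class CycleFitError(Exception):
    """Base class for all cyclefit errors."""


class ArgumentError(CycleFitError, ValueError):
    """Invalid argument or malformed input data."""


class EvaluationError(CycleFitError):
    """A model right-hand side returned non-finite values."""


class IntegrationError(CycleFitError):
    """ODE integration failed (stiffness, blow-up, step-size collapse)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class NoCycleError(CycleFitError):
    """Periodic boundary-value solve did not converge to an orbit."""


class SteadyStateError(CycleFitError):
    """The system settled on a fixed point; period quantities are undefined."""


class DegeneracyError(CycleFitError):
    """Bordered sensitivity system is singular (non-hyperbolic orbit)."""


class EmptyEnsembleError(CycleFitError):
    """Every bootstrap trial was discarded; nothing to analyze."""
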