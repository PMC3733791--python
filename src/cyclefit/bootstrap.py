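"""Bootstrap uncertainty propagation and practical-identifiability reports.

Measurement noise is emulated by redrawing each data point from
Normal(mu = xtilde_i(t_j), sigma_ij) with

    sigma_ij = xi * xtilde_i(t_j) + eta * max_j xtilde_i(t_j)

where xi is the relative and eta the absolute error level.  The same
sigma_ij doubles as the weight of the chi-square fitting cost.  Each of the
B trials re-estimates parameters from an independent noisy dataset; trials
whose NLP fails to converge, or whose fitted orbit has collapsed to a
steady state (where period sensitivities are undefined), are discarded.

A predicted response (relative period sensitivity) is called *practically
identifiable* at level gamma when a fraction >= gamma of its bootstrap
distribution shares one sign.  A second, interval-based rule - the 5th-95th
percentile interval not straddling zero - is reported alongside; the two
differ (the interval rule examines 90% of the mass) and both are in common
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .collocation import (
    PHASE_GRID,
    CollocationConfig,
    EstimateResult,
    estimate_parameters,
)
from .data import TimeSeriesDataset
from .errors import (
    ArgumentError,
    DegeneracyError,
    EmptyEnsembleError,
    IntegrationError,
    SteadyStateError,
)
from .limit_cycle import find_limit_cycle
from .model import OscillatorModel
from .sensitivity import PeriodSensitivity, variational_period_sensitivities

__all__ = [
    "NoiseModel",
    "BootstrapTrial",
    "BootstrapEnsemble",
    "IdentifiabilityReport",
    "sample_true_data",
    "generate_bootstrap_dataset",
    "run_bootstrap",
    "percentile_band",
    "classify_identifiability",
    "compare_models",
]

#: preset emulating optimistic error bars for literature data lacking them
LITERATURE_NOISE_PRESET = {"xi": 0.03, "eta": 0.005}


@dataclass
class NoiseModel:
    """Mixed relative/absolute measurement-error model.

    ``xi`` scales with the signal, ``eta`` with each state's maximum over
    the sampled cycle (so small values are not assigned vanishing error).
    ``clip_negative`` optionally truncates sampled means at zero; by default
    Gaussian tails may produce slightly negative concentrations.
    """

    xi: float
    eta: float = 0.001
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.xi < 0 or self.eta < 0:
            raise ArgumentError("xi and eta must be non-negative")
        if self.xi + self.eta == 0:
            raise ArgumentError("xi + eta must be positive (sigma are cost weights)")

    def sigma(self, true_means: np.ndarray) -> np.ndarray:
        true_means = np.atleast_2d(np.asarray(true_means, dtype=float))
        return self.xi * true_means + self.eta * true_means.max(axis=1, keepdims=True)


def sample_true_data(
    model: OscillatorModel,
    p: np.ndarray,
    n_samples: int,
    cycle=None,
) -> TimeSeriesDataset:
    """Noise-free truth: the limit cycle sampled at M equispaced times on [0, T).

    ``stds`` are left unset; a :class:`NoiseModel` fills them when noisy
    replicates are drawn.  Raises ``SteadyStateError`` if the model does not
    oscillate at ``p``.
    """
    if n_samples < 4:
        raise ArgumentError("need at least 4 sampling points")
    if cycle is None:
        T_hint = model.period_hint or 24.0
        x0 = np.ones(model.neq)
        cycle = find_limit_cycle(model, p, x0, T_hint)
    times = np.linspace(0.0, cycle.period, n_samples, endpoint=False)
    return TimeSeriesDataset(
        times=times,
        means=cycle.sampler(times),
        stds=None,
        state_names=list(model.state_names),
    )


def generate_bootstrap_dataset(
    truth: TimeSeriesDataset,
    noise: NoiseModel,
    seed,
) -> TimeSeriesDataset:
    """One simulated measurement: means ~ Normal(truth, sigma), stds = sigma."""
    if not np.all(np.isfinite(truth.means)):
        raise ArgumentError("truth means must be finite")
    rng = np.random.default_rng(seed)
    sigma = noise.sigma(truth.means)
    if np.any(sigma <= 0):
        raise ArgumentError(
            "noise model yields non-positive sigma; increase eta or check the data"
        )
    means = rng.normal(truth.means, sigma)
    if noise.clip_negative:
        means = np.clip(means, 0.0, None)
    return TimeSeriesDataset(
        times=truth.times.copy(),
        means=means,
        stds=sigma,
        state_names=list(truth.state_names),
    )


@dataclass
class BootstrapTrial:
    """One converged bootstrap trial."""

    index: int
    params: np.ndarray
    period: float
    cost: float
    n_iterations: int
    sensitivities: np.ndarray
    phase_trajectory: np.ndarray   # (NEQ, len(PHASE_GRID))

    def __eq__(self, other) -> bool:
        if not isinstance(other, BootstrapTrial):
            return NotImplemented
        return (
            self.index == other.index
            and np.array_equal(self.params, other.params)
            and self.period == other.period
            and self.cost == other.cost
            and self.n_iterations == other.n_iterations
            and np.array_equal(self.sensitivities, other.sensitivities, equal_nan=True)
            and np.array_equal(self.phase_trajectory, other.phase_trajectory)
        )


@dataclass
class BootstrapEnsemble:
    """Converged trials plus discard bookkeeping.

    Invariant: ``len(results) + n_failed + n_steady == n_requested``.
    """

    results: list
    n_requested: int
    n_failed: int
    n_steady: int
    master_seed: int
    param_names: Sequence[str]
    state_names: Sequence[str]
    phase_grid: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())

    def __post_init__(self) -> None:
        if len(self.results) + self.n_failed + self.n_steady != self.n_requested:
            raise ArgumentError("trial counts do not add up to n_requested")

    @property
    def n_results(self) -> int:
        return len(self.results)

    @property
    def parameters(self) -> np.ndarray:
        """(n_results, NP) matrix of optimal parameter vectors."""
        return np.array([t.params for t in self.results])

    @property
    def periods(self) -> np.ndarray:
        return np.array([t.period for t in self.results])

    @property
    def sensitivities(self) -> np.ndarray:
        """(n_results, NP) matrix of relative period sensitivities."""
        return np.array([t.sensitivities for t in self.results])

    def __eq__(self, other) -> bool:
        if not isinstance(other, BootstrapEnsemble):
            return NotImplemented
        return (
            self.results == other.results
            and self.n_requested == other.n_requested
            and self.n_failed == other.n_failed
            and self.n_steady == other.n_steady
            and self.master_seed == other.master_seed
            and list(self.param_names) == list(other.param_names)
            and list(self.state_names) == list(other.state_names)
            and np.array_equal(self.phase_grid, other.phase_grid)
        )


def trial_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based per-trial seed: identical streams under any execution order."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))


def _run_one_trial(args) -> tuple[int, str, BootstrapTrial | None]:
    model, truth, noise, config, master_seed, index = args
    dataset = generate_bootstrap_dataset(truth, noise, trial_seed(master_seed, index))
    est = estimate_parameters(model, dataset, config)
    if est.status != "converged":
        return index, est.status, None
    try:
        sens = variational_period_sensitivities(model, est.cycle, est.p_star)
    except (DegeneracyError, IntegrationError):
        # periodic sensitivities undefined: treat like a steady-state discard
        return index, "steady_state", None
    trial = BootstrapTrial(
        index=index,
        params=est.p_star,
        period=est.period,
        cost=est.cost,
        n_iterations=est.n_iterations,
        sensitivities=sens.values,
        phase_trajectory=est.phase_trajectory,
    )
    return index, "converged", trial


def run_bootstrap(
    model: OscillatorModel,
    truth: TimeSeriesDataset,
    noise: NoiseModel,
    n_trials: int,
    config: CollocationConfig | None = None,
    master_seed: int = 0,
    map_fn: Callable[..., Iterable] = map,
    progress: Callable[[int, str], None] | None = None,
) -> BootstrapEnsemble:
    """Run B independent estimation trials on regenerated noisy datasets.

    Per-trial seeds derive deterministically from ``master_seed`` and the
    trial index, so any parallel ``map_fn`` (e.g.
    ``multiprocessing.Pool.imap``) reproduces the serial result exactly.
    """
    if n_trials < 1:
        raise ArgumentError("n_trials must be >= 1")
    config = config or CollocationConfig()
    jobs = [(model, truth, noise, config, master_seed, b) for b in range(n_trials)]
    results: list[BootstrapTrial] = []
    n_failed = n_steady = 0
    for index, status, trial in map_fn(_run_one_trial, jobs):
        if progress is not None:
            progress(index, status)
        if status == "converged":
            results.append(trial)
        elif status == "steady_state":
            n_steady += 1
        else:
            n_failed += 1
    results.sort(key=lambda t: t.index)
    if not results:
        raise EmptyEnsembleError(
            f"all {n_trials} bootstrap trials were discarded "
            f"({n_failed} failed, {n_steady} steady-state)"
        )
    return BootstrapEnsemble(
        results=results,
        n_requested=n_trials,
        n_failed=n_failed,
        n_steady=n_steady,
        master_seed=int(master_seed),
        param_names=list(model.param_names),
        state_names=list(model.state_names),
    )


def percentile_band(
    ensemble: BootstrapEnsemble,
    state: str,
    grid: np.ndarray,
    lo: float = 5.0,
    hi: float = 95.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise percentile envelope of the fitted one-period trajectories.

    Each trial's orbit is stored on its own normalized phase grid; the
    requested time ``grid`` is normalized to phase by its span and every
    member is evaluated there (periodic linear interpolation) before taking
    pointwise empirical percentiles (linear interpolation between order
    statistics).  Orbits are phase-aligned by their common anchor
    convention (maximum of the first state).
    """
    if ensemble.n_results == 0:
        raise ArgumentError("ensemble has no converged results")
    if not 0 <= lo < hi <= 100:
        raise ArgumentError("need 0 <= lo < hi <= 100")
    try:
        i_state = list(ensemble.state_names).index(state)
    except ValueError:
        raise ArgumentError(
            f"unknown state {state!r}; have {list(ensemble.state_names)}"
        ) from None
    grid = np.asarray(grid, dtype=float)
    span = grid[-1] - grid[0]
    if span <= 0:
        raise ArgumentError("grid must span a positive interval")
    phases = np.mod((grid - grid[0]) / span, 1.0 + 1e-15)
    curves = np.array([
        np.interp(phases, ensemble.phase_grid, t.phase_trajectory[i_state])
        for t in ensemble.results
    ])
    lower = np.percentile(curves, lo, axis=0)
    upper = np.percentile(curves, hi, axis=0)
    return lower, upper


@dataclass
class IdentifiabilityReport:
    """Per-parameter distribution summaries and identifiability flags."""

    param_names: Sequence[str]
    level: float
    n_results: int
    low_power: bool
    param_quantiles: np.ndarray        # (NP, 2): 5th/95th of p_star
    param_medians: np.ndarray
    sens_quantiles: np.ndarray         # (NP, 2): 5th/95th of sensitivities
    sens_medians: np.ndarray
    sign_consistent_fraction: np.ndarray
    identifiable: np.ndarray           # fraction rule at `level` (default)
    identifiable_interval: np.ndarray  # 5th-95th interval does not span zero
    quantile_probs: tuple = (5.0, 95.0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IdentifiabilityReport):
            return NotImplemented
        return (
            list(self.param_names) == list(other.param_names)
            and self.level == other.level
            and self.n_results == other.n_results
            and self.low_power == other.low_power
            and np.array_equal(self.param_quantiles, other.param_quantiles)
            and np.array_equal(self.param_medians, other.param_medians)
            and np.array_equal(self.sens_quantiles, other.sens_quantiles,
                               equal_nan=True)
            and np.array_equal(self.sens_medians, other.sens_medians, equal_nan=True)
            and np.array_equal(self.sign_consistent_fraction,
                               other.sign_consistent_fraction)
            and np.array_equal(self.identifiable, other.identifiable)
            and np.array_equal(self.identifiable_interval, other.identifiable_interval)
            and tuple(self.quantile_probs) == tuple(other.quantile_probs)
        )


def classify_identifiability(
    ensemble: BootstrapEnsemble,
    level: float = 0.95,
    quantile_probs: tuple[float, float] = (5.0, 95.0),
    min_results: int = 20,
) -> IdentifiabilityReport:
    """Classify which predicted responses keep a consistent sign.

    The default rule flags a sensitivity identifiable when at least
    ``level`` of its bootstrap distribution shares one sign.  The
    interval rule (quantile interval not straddling zero) is reported
    alongside.  Reports are flagged ``low_power`` below ``min_results``
    converged trials.
    """
    if ensemble.n_results == 0:
        raise ArgumentError("ensemble has no converged results")
    if not 0.5 < level < 1.0:
        raise ArgumentError("level must lie in (0.5, 1)")
    sens = ensemble.sensitivities
    params = ensemble.parameters
    lo, hi = quantile_probs
    frac_pos = np.mean(sens > 0, axis=0)
    frac_neg = np.mean(sens < 0, axis=0)
    frac = np.maximum(frac_pos, frac_neg)
    sens_q = np.column_stack([
        np.nanpercentile(sens, lo, axis=0),
        np.nanpercentile(sens, hi, axis=0),
    ])
    spans_zero = (sens_q[:, 0] < 0) & (sens_q[:, 1] > 0)
    return IdentifiabilityReport(
        param_names=list(ensemble.param_names),
        level=float(level),
        n_results=ensemble.n_results,
        low_power=ensemble.n_results < min_results,
        param_quantiles=np.column_stack([
            np.percentile(params, lo, axis=0),
            np.percentile(params, hi, axis=0),
        ]),
        param_medians=np.median(params, axis=0),
        sens_quantiles=sens_q,
        sens_medians=np.nanmedian(sens, axis=0),
        sign_consistent_fraction=frac,
        identifiable=frac >= level,
        identifiable_interval=~spans_zero,
        quantile_probs=(float(lo), float(hi)),
    )


def compare_models(
    report_a: IdentifiabilityReport,
    report_b: IdentifiabilityReport,
    mapping: Sequence[tuple[str, str]],
) -> list[dict]:
    """Cross-model consistency of shared predicted responses.

    A pair is *robust* when the response is identifiable in both models and
    the median sensitivities share the same sign - i.e. the prediction
    survives a change of model structure.
    """
    rows = []
    names_a = list(report_a.param_names)
    names_b = list(report_b.param_names)
    for name_a, name_b in mapping:
        if name_a not in names_a:
            raise ArgumentError(f"{name_a!r} not in first report")
        if name_b not in names_b:
            raise ArgumentError(f"{name_b!r} not in second report")
        ia, ib = names_a.index(name_a), names_b.index(name_b)
        ident_a = bool(report_a.identifiable[ia])
        ident_b = bool(report_b.identifiable[ib])
        sign_a = float(np.sign(report_a.sens_medians[ia]))
        sign_b = float(np.sign(report_b.sens_medians[ib]))
        rows.append({
            "response_a": name_a,
            "response_b": name_b,
            "identifiable_a": ident_a,
            "identifiable_b": ident_b,
            "median_sign_a": sign_a,
            "median_sign_b": sign_b,
            "robust": ident_a and ident_b and sign_a == sign_b and sign_a != 0.0,
        })
    return rows
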