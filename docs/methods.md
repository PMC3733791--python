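# Methods

## Model class and fixtures

`cyclefit` works on autonomous ODE models dx/dt = f(x, p) with strictly
positive kinetic parameters and an attracting limit cycle x(t) = x(t + T),
T > 0 the fundamental period. Models are dimensionless internally; the time
unit is whatever the data uses (hours in the circadian-flavoured examples).

The reference fixture is a three-state Goodwin negative-feedback loop,

    dx1/dt = a/(1 + x3^n) − b·x1        (mRNA)
    dx2/dt = c·x1 − d·x2                (cytosolic protein)
    dx3/dt = e·x2 − g·x3                (nuclear repressor)

with the Hill exponent n a structural constant, not an estimated parameter.
Sustained oscillation of this loop needs high cooperativity (n ≳ 8 for
comparable degradation rates); the fixture uses n = 10 with nominal rates
(a, b, c, d, e, g) = (4, 0.2, 1, 0.2, 1, 0.2), which simulation shows to
yield a stable cycle of period T ≈ 19.81 with peak-to-peak amplitudes of
about 0.17, 0.40 and 1.05. These constants are a design choice verified by
the test suite (long integrations from perturbed starts converge to a
non-constant periodic orbit), chosen to put amplitudes at order one and the
period near the circadian scale while keeping round numbers. The damped
control (`damped_fixture`) is the same loop at n = 2 with rates
(1, 0.1, 1, 0.1, 1, 0.1): its fixed point is globally stable, which
exercises steady-state detection and trial discarding.

Two structural facts about the fixture double as exact test oracles:

* every parameter is a multiplicative rate, so f(x, λp) = λ·f(x, p) and
  T(λp) = T(p)/λ, forcing Σ_k ∂lnT/∂ln p_k = −1;
* rescaling x1 or x2 maps orbits to orbits (the Hill term pins x3's scale),
  so T depends on (a, c, e) only through the product a·c·e and their three
  relative sensitivities are exactly equal.

## Periodic-orbit solve

`find_limit_cycle` integrates through the transient (default 10 period
guesses, LSODA with rtol 1e-8 / atol 1e-10 and the analytic state Jacobian
when the model provides one), anchors the guess at a maximum of state 1,
then runs a damped Newton iteration on the single-shooting residual

    R(x0, T) = [ x(T; x0) − x0 ;  f1(x0, p) ]

with Jacobian [M − I, f(x(T)); ∂f1/∂x, 0], M the monodromy matrix from the
variational equations. Convergence is ‖R‖ ≤ 1e-8·(1 + ‖x0‖) within 50
iterations. The phase condition f1(x0, p) = 0 at an x1 maximum removes the
time-translation degeneracy; the anchor is placed by event detection
(downward zero crossing of f1) so the second-order condition holds by
construction. The returned period is checked to be fundamental by verifying
that the half-period map moves the anchor; if not, T is halved and
re-polished. Orbits whose relative peak-to-peak amplitude falls below 1e-3
(against each state's mean magnitude) raise a steady-state error; Newton
non-convergence raises a no-cycle error. A warm-start variant
(`refine_limit_cycle`) skips the transient and is used after collocation
fits and inside finite-difference loops.

`estimate_period` implements the sampling design used throughout: data are
assumed to cover exactly one cycle at M equispaced points, so the period
guess is the grid span plus one sampling interval. Flat data (maximum
relative range < 1%) are rejected rather than guessed at.

## Collocation transcription

The fit works on normalized phase τ = t/T ∈ [0, 1], with dynamics
dx/dτ = T·f(x, p). The orbit is divided into N uniform elements, each
carrying a Lagrange polynomial through K+1 nodes: the element start plus K
Radau (right-endpoint) collocation points — the roots of the Jacobi
polynomial P_{K−1}^{(1,0)} mapped to (0, 1), plus 1. Radau points are
stiff-stable and make the element-end state an explicit variable, so
continuity and periodicity constraints are linear. Decision variables are
the states at all N(K+1) nodes — (N)(K+1)(NEQ) + NP in the conventional
count — plus the log-parameters and, as one extra variable, the period T.
Carrying T explicitly (rather than freezing it at the data span) costs one
variable and lets real datasets determine their own period; data times map
to τ_j = t_j/T inside the cost, so the cost gradient carries ∂τ/∂T terms.

Equality constraints per element: the collocation equations
Σ_j L_j'(c_k)·x_{e,j} = (T/N)·f(x_{e,k}, p) at each Radau point, plus
continuity x_{e+1,0} = x_{e,K} and periodic closure x_{0,0} = x_{N−1,K}.
Missing individual data points (NaN means) simply drop out of the cost;
entirely unmeasured states are rejected, since the data-driven initial
guess requires all states observed (systems with latent states need an
externally supplied guess).

The NLP is solved with SLSQP using analytic cost gradients and constraint
Jacobians (model Jacobians analytic for the fixtures, central finite
differences otherwise). Parameters are optimized in log space with bounds
[guess/10³, guess·10³]; the period within [guess/2, 2·guess]. Convergence
means solver success with maximum constraint violation ≤ 1e-6 (the solver
restarts from its own iterate up to twice before giving up); anything else
is status `failed`. The initial guess interpolates the data with a periodic
cubic spline onto the collocation grid, takes nominal (or user) parameters,
and the span-based period estimate.

Defaults N = 12, K = 4 were chosen by a convergence scan on the fixture:
they keep the collocation trajectory within 1e-4 relative max-norm of a
high-accuracy re-integration over one period (the consistency invariant the
tests enforce) at roughly 0.15 s per fit; doubling N changes recovered
parameters by < 0.1%. After a successful solve the orbit is re-solved with
the shooting Newton from the first collocation node, which re-anchors the
phase, verifies non-degeneracy (else status `steady_state`) and provides
the dense trajectory stored for percentile bands.

## Period sensitivities

Relative sensitivities s_k = (p_k/T)·dT/dp_k are obtained by
differentiating the shooting residual. With S_p = ∂x(T)/∂p (parametric
variational equations, initial value 0) and M the monodromy matrix, the
bordered linear system

    [ M − I   f(x0) ] [ dx0/dp ]     [ S_p       ]
    [ ∂f1/∂x    0   ] [ dT/dp  ]  = −[ ∂f1/∂p    ]

is solved directly; its condition number is reported, and values beyond
1e10 raise a degeneracy error (a Floquet multiplier near 1 beyond the
trivial one). This is exact to integration tolerance (rtol 1e-9) and costs
one combined integration of NEQ·(1 + NEQ + NP) equations.

The independent oracle `fd_period_sensitivities` re-solves the orbit at
p_k·(1 ± r) (default r = 1e-3, warm-started, integration tolerances
tightened to rtol 1e-11 so oracle noise sits near 1e-6) and returns
(lnT₊ − lnT₋)/(2r). The test suite requires the two routes to agree within
1e-3 relative (1e-6 absolute floor) on the fixture and on 20 random
oscillatory parameter draws; sensitivities are anchor-invariant to 1e-6.
A parameter whose perturbation destroys the oscillation is flagged
undefined (NaN) rather than extrapolated.

`finite_ratio_sensitivity` is the experimental calibration helper: a 5%
period change produced by a 50% rate change corresponds to a measurable
sensitivity magnitude of 0.1, a useful yardstick for which model responses
are experimentally verifiable at all.

## Noise model and bootstrap

Simulated measurements redraw each point from Normal(x̃_i(t_j), σ_ij) with

    σ_ij = ξ·x̃_i(t_j) + η·max_j x̃_i(t_j),

ξ the relative and η the absolute error level. The absolute term (default
η = 0.001) keeps σ positive where trajectories approach zero — essential
because the same σ_ij serve as the weights of the chi-square cost, and
near-zero values would otherwise dominate it. Sampled means are *not*
truncated at zero (Gaussian tails may produce small negative
concentrations); a `clip_negative` flag is available for users who prefer
truncation. A preset (ξ = 0.03, η = 0.005) mirrors the optimistic error
model commonly assumed for literature time courses that lack error bars.

Each of the B trials draws its own dataset from a counter-based seed
(`SeedSequence(master_seed, spawn_key=(trial,))`), fits it, and on success
computes variational sensitivities. Trials are discarded — and counted —
as `failed` (NLP non-convergence) or `steady_state` (degenerate fitted
orbit, where periodic sensitivities are undefined). Because seeds are
per-trial, any order-preserving parallel map (`map_fn` argument)
reproduces the serial ensemble bit-for-bit; full runs serialize to
byte-identical JSON under a fixed master seed. The library default is
B = 200 at desk scale; study-scale runs (B = 2000) are a CLI flag away but
were not needed to resolve the 5th/95th quantiles used here.

Identifiability is classified two ways, both reported: the default
fraction rule (≥ γ of the distribution shares one sign, γ = 0.95) and the
interval rule (the 5th–95th percentile interval does not straddle zero).
They differ — the interval rule inspects only 90% of the mass — and both
are in common use, so the report exposes both flags plus the raw
sign-consistent fraction. Quantiles use linear interpolation between order
statistics, so brute-force checks match exactly. Reports from fewer than
20 converged trials are flagged low-power. `compare_models` marks a
response *robust* when it is identifiable in two structurally different
models with the same median sign.

## What the synthetic generator does and does not emulate

`sample_true_data` takes noise-free truth from the model's own limit cycle
at M equispaced points over one period, and the noise model above is
Gaussian, independent across points and states, with known σ. Real data
violate all three idealizations: errors correlate across time, σ must be
estimated, sampling is irregular and rarely spans exactly one period, and
not all states are measured. Passing tests therefore demonstrate correct
propagation of *stated* measurement uncertainty through the estimator —
not robustness to model misspecification or structured noise. The
degradation study (interval widths growing with ξ ∈ {0.01, 0.10, 0.30} at
M = 20, shrinking with M ∈ {5, 10, 30} at ξ = 0.15, η = 0.001 throughout)
uses B = 100 trials per condition, enough to order median interval widths
stably while keeping the whole suite at desk scale.

## Numerical choices and degenerate inputs

* Integration: LSODA, rtol 1e-8 / atol 1e-10 (1e-9/1e-11 for variational
  systems, 1e-11/1e-13 inside the FD oracle); analytic Jacobians used when
  the model supplies them.
* Shooting: tol 1e-8, max 50 iterations, step halving (≤ 6) on residual
  increase; minimum-period floor 1e-3 of the guess rejects spurious roots.
* NLP: SLSQP, ftol 1e-10, ≤ 500 iterations, ≤ 2 restarts; constraint
  tolerance 1e-6; log-scaled parameters.
* Steady-state threshold: relative amplitude 1e-3 (with a 1e-12 absolute
  floor on the magnitude scale) both for trajectory flatness and fitted
  orbits.
* Quantiles: linear interpolation; JSON floats via shortest round-trip
  repr with sorted keys (byte-stable output); CSV written at 17
  significant digits and parsed with round-trip precision.
* Degenerate inputs raise typed errors: flat data (period estimation),
  all-missing states (initial guess), non-positive σ (cost weights),
  ξ + η = 0 (noise model), empty ensembles (all trials discarded).

## Known limitations

* Local estimation only: the method's premise is that complete time-series
  data furnish a good initial guess. No multistart/global stage, no
  support for unmeasured states beyond accepting an external guess.
* Single shooting for the standalone orbit solve; fine for the small,
  mildly stiff fixtures here but less robust than multiple shooting for
  strongly unstable orbits.
* Uniform element mesh; sharp-pulse oscillators may need more elements
  than the default rather than adaptive placement.
* The bootstrap treats σ_ij as known; uncertainty in the error model
  itself is not propagated.
* No continuation/bifurcation tracking, phase-response curves, amplitude
  sensitivities, or SBML import.
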