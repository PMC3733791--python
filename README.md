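# cyclefit

Bootstrap uncertainty analysis for limit-cycle models of biological
oscillators.

Kinetic models of gene-regulatory oscillators — circadian clocks, the cell
cycle, metabolic rhythms — are systems of autonomous ODEs

    dx/dt = f(x(t), p)

whose parameters **p** (transcription, translation, transport and
degradation rates) must be estimated from periodic time-series data. The
quantity modellers actually care about is usually not **p** itself but the
predicted *response to perturbation*, summarized by relative period
sensitivities

    s_k = ∂ln T / ∂ln p_k

(fractional period change per fractional change in rate k). Because
measurement noise propagates nonlinearly into both **p⋆** and **s**, and
because limit-cycle existence is a discontinuous function of **p**,
standard Fisher-information confidence intervals are unreliable here.
`cyclefit` instead:

1. **fits** the limit cycle by direct transcription: the period-normalized
   orbit is discretized into N finite elements with degree-K Radau
   collocation polynomials, and the weighted least-squares cost

       p⋆ = argmin_p Σ_i Σ_j ( x̂_i(t_j) − x_i(t_j, p) )² / σ_ij²

   is minimized subject to the collocation dynamics, element continuity and
   periodic closure — a sparse-structured NLP whose initial guess comes
   straight from the data, so convergence is fast and local;
2. **propagates uncertainty** with a parametric bootstrap: B simulated
   datasets are redrawn from Normal(x̃_i(t_j), σ_ij) with
   σ_ij = ξ·x̃_i(t_j) + η·max_j x̃_i(t_j), each is re-fit, and trials that
   fail to converge or collapse to a steady state (where period
   sensitivities are undefined) are discarded;
3. **classifies identifiability**: a predicted response is *practically
   identifiable* when ≥ 95% of its bootstrap distribution keeps one sign —
   i.e. the data constrain at least the direction of the model's response.

Period sensitivities are computed by differentiating the periodic shooting
residual through the monodromy matrix (variational equations), with an
independent finite-difference oracle for cross-checking. A three-state
Goodwin negative-feedback oscillator ships as the reference fixture, so the
whole pipeline runs out of the box with no external data.

This is aimed at systems-biology modellers who want to state, quantitatively,
which of a model's predicted responses follow from the data and which hinge
on the particular parameter values chosen — and at experimental design:
how many time points, at what error level, are needed to make a target
response identifiable.

## Worked example

```python
import numpy as np
import cyclefit as cf

model = cf.goodwin_fixture()
cycle = cf.find_limit_cycle(model, model.nominal_params, np.ones(3), model.period_hint)
print(f"nominal period: {cycle.period:.4f} h")

truth = cf.sample_true_data(model, model.nominal_params, 20, cycle=cycle)
ensemble = cf.run_bootstrap(
    model, truth, cf.NoiseModel(xi=0.10, eta=0.001), 100, master_seed=1
)
print(f"converged trials: {ensemble.n_results}/100 "
      f"(failed {ensemble.n_failed}, steady {ensemble.n_steady})")

report = cf.classify_identifiability(ensemble, level=0.95)
for name, med, (lo, hi), frac, ident in zip(
    report.param_names, report.sens_medians, report.sens_quantiles,
    report.sign_consistent_fraction, report.identifiable,
):
    print(f"dlnT/dln {name}: median {med:+.4f}  5-95% [{lo:+.4f}, {hi:+.4f}]  "
          f"sign-consistent {frac:.2f}  identifiable={bool(ident)}")
```

prints

```
nominal period: 19.8087 h
converged trials: 100/100 (failed 0, steady 0)
dlnT/dln a: median +0.0028  5-95% [+0.0020, +0.0038]  sign-consistent 1.00  identifiable=True
dlnT/dln b: median -0.3398  5-95% [-0.3963, -0.3143]  sign-consistent 1.00  identifiable=True
dlnT/dln c: median +0.0028  5-95% [+0.0020, +0.0038]  sign-consistent 1.00  identifiable=True
dlnT/dln d: median -0.3435  5-95% [-0.3979, -0.2870]  sign-consistent 1.00  identifiable=True
dlnT/dln e: median +0.0028  5-95% [+0.0020, +0.0038]  sign-consistent 1.00  identifiable=True
dlnT/dln g: median -0.3242  5-95% [-0.3697, -0.2288]  sign-consistent 1.00  identifiable=True
```

Reading this: at 10% relative error and 20 samples per cycle, every response
direction of the Goodwin loop is identifiable. The period lengthens when any
degradation rate (b, d, g) slows — each carries about a third of the total —
while the three production rates (a, c, e) matter only through their product
(a consequence of state-rescaling symmetry) and have a tiny, but still
sign-consistent, positive effect. The sensitivities over all six rates sum
to −1, the exact signature of a pure-rate parameterization: doubling every
rate halves the period.

The same pipeline is scriptable from the shell:

```sh
echo "model: goodwin" > goodwin.yaml
cyclefit bootstrap --model goodwin.yaml --xi 0.10 --trials 100 --seed 1 --out ens.json
cyclefit report --ensemble ens.json --level 0.95 --out report.json --plot violins.png
cyclefit sweep --model goodwin.yaml --trials 100 --out-dir sweep/   # noise/sampling grid
```

Custom models plug in programmatically as `OscillatorModel(state_names,
param_names, rhs, nominal_params, ...)`; datasets are plain CSV with a
`time` column and `<state>_mean` / `<state>_std` pairs.

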