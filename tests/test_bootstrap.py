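import numpy as np
import pytest

import cyclefit as cf
from cyclefit.bootstrap import BootstrapTrial, trial_seed


def toy_ensemble(sens_samples, n_phase=11):
    """Hand-built one-parameter ensemble with prescribed sensitivity draws."""
    phase = np.linspace(0.0, 1.0, n_phase)
    trials = [
        BootstrapTrial(
            index=i,
            params=np.array([1.0 + 0.1 * i]),
            period=20.0,
            cost=1.0,
            n_iterations=5,
            sensitivities=np.array([s]),
            phase_trajectory=np.vstack([np.sin(2 * np.pi * phase) + 0.01 * i]),
        )
        for i, s in enumerate(sens_samples)
    ]
    return cf.BootstrapEnsemble(
        results=trials,
        n_requested=len(trials),
        n_failed=0,
        n_steady=0,
        master_seed=0,
        param_names=["k"],
        state_names=["x1"],
        phase_grid=phase,
    )


class TestNoiseModel:
    def test_zero_noise_rejected(self):
        with pytest.raises(cf.ArgumentError):
            cf.NoiseModel(xi=0.0, eta=0.0)

    def test_sigma_formula_at_zero_value(self):
        # eta couples to the state's maximum: sigma = 0.001 * 2.0 at value 0
        noise = cf.NoiseModel(xi=0.1, eta=0.001)
        means = np.array([[0.0, 1.0, 2.0]])
        np.testing.assert_allclose(noise.sigma(means)[0, 0], 0.002)

    def test_sigma_mixes_relative_and_absolute(self):
        noise = cf.NoiseModel(xi=0.1, eta=0.01)
        means = np.array([[1.0, 4.0]])
        np.testing.assert_allclose(noise.sigma(means), [[0.14, 0.44]])


class TestSampleTrueData:
    def test_shape_and_values(self, goodwin, goodwin_cycle):
        truth = cf.sample_true_data(goodwin, goodwin.nominal_params, 20, cycle=goodwin_cycle)
        assert truth.n_samples == 20
        assert truth.stds is None
        np.testing.assert_array_equal(truth.means, goodwin_cycle.sampler(truth.times))

    def test_virtual_wraparound_point(self, goodwin, goodwin_cycle):
        truth = cf.sample_true_data(goodwin, goodwin.nominal_params, 20, cycle=goodwin_cycle)
        dt = truth.times[1] - truth.times[0]
        wrap = goodwin_cycle.sampler(truth.times[-1] + dt)
        assert np.max(np.abs(wrap - truth.means[:, 0])) < 1e-7

    def test_steady_model_rejected(self, damped):
        with pytest.raises(cf.SteadyStateError):
            cf.sample_true_data(damped, damped.nominal_params, 10)


class TestGenerateBootstrapDataset:
    def test_deterministic_given_seed(self, truth30):
        noise = cf.NoiseModel(xi=0.1, eta=0.001)
        a = cf.generate_bootstrap_dataset(truth30, noise, 99)
        b = cf.generate_bootstrap_dataset(truth30, noise, 99)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.stds, b.stds)

    def test_moments_match_noise_model(self):
        # Monte Carlo moment check at a single (state, time) cell
        truth = cf.TimeSeriesDataset(np.arange(4.0), np.array([[2.0, 3.0, 4.0, 5.0]]))
        noise = cf.NoiseModel(xi=0.1, eta=0.0)
        draws = np.array([
            cf.generate_bootstrap_dataset(truth, noise, seed).means[0, 0]
            for seed in range(10_000)
        ])
        sigma = 0.1 * 2.0
        se = sigma / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se
        assert abs(draws.std() / sigma - 1.0) < 0.05

    def test_clipping_flag(self, truth30):
        noise = cf.NoiseModel(xi=2.0, eta=0.001, clip_negative=True)
        ds = cf.generate_bootstrap_dataset(truth30, noise, 0)
        assert np.all(ds.means >= 0.0)


@pytest.fixture(scope="module")
def small_ensemble(goodwin, truth30):
    return cf.run_bootstrap(
        goodwin, truth30, cf.NoiseModel(xi=0.05, eta=0.001), 8, master_seed=2024
    )


class TestRunBootstrap:
    def test_count_conservation(self, small_ensemble):
        assert (
            small_ensemble.n_results
            + small_ensemble.n_failed
            + small_ensemble.n_steady
            == small_ensemble.n_requested
        )

    def test_master_seed_determinism(self, goodwin, truth30, small_ensemble):
        again = cf.run_bootstrap(
            goodwin, truth30, cf.NoiseModel(xi=0.05, eta=0.001), 8, master_seed=2024
        )
        assert again == small_ensemble

    def test_trial_seeds_are_counter_based(self):
        a = np.random.default_rng(trial_seed(7, 3)).uniform(size=4)
        b = np.random.default_rng(trial_seed(7, 3)).uniform(size=4)
        c = np.random.default_rng(trial_seed(7, 4)).uniform(size=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_parameters_recovered_at_low_noise(self, small_ensemble, goodwin):
        med = np.median(small_ensemble.parameters, axis=0)
        assert np.max(np.abs(med / goodwin.nominal_params - 1.0)) < 0.15

    def test_parallel_map_reproduces_serial(self, goodwin, truth30, small_ensemble):
        # any order-preserving map must give the identical ensemble
        def shuffled_map(fn, jobs):
            jobs = list(jobs)
            return [fn(j) for j in reversed(jobs)]

        ens = cf.run_bootstrap(
            goodwin, truth30, cf.NoiseModel(xi=0.05, eta=0.001), 8,
            master_seed=2024, map_fn=shuffled_map,
        )
        assert ens == small_ensemble


class TestPercentileBand:
    def test_identical_members_have_zero_width(self):
        ens = toy_ensemble([0.5] * 5)
        for t in ens.results:
            t.phase_trajectory = ens.results[0].phase_trajectory.copy()
        lo, hi = cf.percentile_band(ens, "x1", np.linspace(0, 20, 30))
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-15)

    def test_full_band_is_an_envelope(self):
        ens = toy_ensemble([0.1, 0.2, 0.3, 0.4, 0.5])
        grid = np.linspace(0.0, 20.0, 25)
        lo, hi = cf.percentile_band(ens, "x1", grid, 0.0, 100.0)
        phases = (grid - grid[0]) / (grid[-1] - grid[0])
        for t in ens.results:
            member = np.interp(phases % 1.0, ens.phase_grid, t.phase_trajectory[0])
            assert np.all(member >= lo - 1e-12)
            assert np.all(member <= hi + 1e-12)

    def test_matches_brute_force_percentile(self):
        ens = toy_ensemble([0.1, 0.2, 0.3, 0.4, 0.5])
        grid = ens.phase_grid * 20.0
        lo, hi = cf.percentile_band(ens, "x1", grid, 5, 95)
        stack = np.vstack([t.phase_trajectory[0] for t in ens.results])
        np.testing.assert_allclose(lo, np.percentile(stack, 5, axis=0), atol=1e-12)
        np.testing.assert_allclose(hi, np.percentile(stack, 95, axis=0), atol=1e-12)

    def test_unknown_state(self):
        with pytest.raises(cf.ArgumentError):
            cf.percentile_band(toy_ensemble([0.1]), "nope", np.linspace(0, 1, 5))


class TestClassifyIdentifiability:
    def test_all_positive_is_identifiable(self):
        rep = cf.classify_identifiability(toy_ensemble([0.1] * 30), level=0.95)
        assert rep.identifiable[0]
        assert rep.sign_consistent_fraction[0] == 1.0

    def test_symmetric_distribution_is_not(self):
        samples = [0.1, -0.1] * 15
        rep = cf.classify_identifiability(toy_ensemble(samples), level=0.95)
        assert not rep.identifiable[0]
        assert rep.sign_consistent_fraction[0] == pytest.approx(0.5)

    def test_96_to_4_split_depends_on_level(self):
        samples = [1.0] * 96 + [-1.0] * 4
        at_95 = cf.classify_identifiability(toy_ensemble(samples), level=0.95)
        at_97 = cf.classify_identifiability(toy_ensemble(samples), level=0.97)
        assert at_95.identifiable[0]
        assert not at_97.identifiable[0]

    def test_low_power_flag(self):
        rep = cf.classify_identifiability(toy_ensemble([0.1] * 5), level=0.95)
        assert rep.low_power

    def test_interval_rule_differs_from_fraction_rule(self):
        # 92% positive mass: sign-consistent fraction fails gamma=0.95 but the
        # 5th-95th interval still sits above zero on one side
        samples = [1.0] * 92 + [-1.0] * 8
        rep = cf.classify_identifiability(toy_ensemble(samples), level=0.95)
        assert not rep.identifiable[0]
        assert not rep.identifiable_interval[0]
        samples = [1.0] * 96 + [-1.0] * 4
        rep = cf.classify_identifiability(toy_ensemble(samples), level=0.95)
        assert rep.identifiable_interval[0]


class TestCompareModels:
    def test_identical_reports_are_robust(self):
        rep = cf.classify_identifiability(toy_ensemble([0.2] * 25), level=0.95)
        rows = cf.compare_models(rep, rep, [("k", "k")])
        assert rows[0]["robust"]

    def test_non_identifiable_side_breaks_robustness(self):
        good = cf.classify_identifiability(toy_ensemble([0.2] * 25), level=0.95)
        bad = cf.classify_identifiability(toy_ensemble([0.2, -0.2] * 13), level=0.95)
        rows = cf.compare_models(good, bad, [("k", "k")])
        assert not rows[0]["robust"]

    def test_sign_clash_breaks_robustness(self):
        pos = cf.classify_identifiability(toy_ensemble([0.2] * 25), level=0.95)
        neg = cf.classify_identifiability(toy_ensemble([-0.2] * 25), level=0.95)
        rows = cf.compare_models(pos, neg, [("k", "k")])
        assert rows[0]["identifiable_a"] and rows[0]["identifiable_b"]
        assert not rows[0]["robust"]

    def test_unknown_name_rejected(self):
        rep = cf.classify_identifiability(toy_ensemble([0.2] * 25), level=0.95)
        with pytest.raises(cf.ArgumentError):
            cf.compare_models(rep, rep, [("nope", "k")])
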