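import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial import legendre

import cyclefit as cf
from conftest import GOODWIN_PERIOD


def radau_points_oracle(degree):
    """Right Gauss-Radau points on (0, 1] by brute-force root finding.

    The abscissae on [-1, 1] (right endpoint fixed) are the roots of
    P_K(x) - P_{K-1}(x); map them to (0, 1].
    """
    coeffs = np.zeros(degree + 1)
    coeffs[degree] = 1.0
    coeffs[degree - 1] -= 1.0
    roots = legendre.legroots(coeffs)
    return np.sort((np.real(roots) + 1.0) / 2.0)


class TestCollocationPoints:
    def test_degree_one_is_implicit_euler(self):
        basis = cf.collocation_points(1)
        np.testing.assert_allclose(basis.points, [1.0])

    @pytest.mark.parametrize("degree", [2, 3, 5])
    def test_points_match_root_finding_oracle(self, degree):
        basis = cf.collocation_points(degree)
        np.testing.assert_allclose(basis.points, radau_points_oracle(degree), atol=1e-10)

    def test_degree_three_closed_form(self):
        basis = cf.collocation_points(3)
        exact = np.array([(4 - np.sqrt(6)) / 10, (4 + np.sqrt(6)) / 10, 1.0])
        np.testing.assert_allclose(basis.points, exact, atol=1e-12)

    @pytest.mark.parametrize("degree", [1, 2, 4, 6])
    def test_polynomial_exactness(self, degree):
        # the Lagrange basis through the K+1 nodes reproduces t^K exactly
        basis = cf.collocation_points(degree)
        vals = basis.nodes**degree
        rng = np.random.default_rng(5)
        for s in rng.uniform(0.0, 1.0, size=10):
            assert abs(basis.values(s) @ vals - s**degree) < 1e-12

    def test_differentiation_matrix(self):
        # D applied to node values of t^2 gives the derivative 2t at the points
        basis = cf.collocation_points(3)
        vals = basis.nodes**2
        np.testing.assert_allclose(vals @ basis.diff_matrix, 2 * basis.points, atol=1e-12)

    def test_unsupported_scheme(self):
        with pytest.raises(cf.ArgumentError):
            cf.collocation_points(3, scheme="chebyshev")


class TestCountDecisionVariables:
    @pytest.mark.parametrize("args,expected", [
        ((20, 5, 8, 21), 981),
        ((1, 1, 1, 0), 2),
        ((3, 2, 4, 5), 41),
    ])
    def test_formula(self, args, expected):
        assert cf.count_decision_variables(*args) == expected


class TestCost:
    def test_perfect_fit_is_zero(self, quiet_dataset):
        assert cf.cost(quiet_dataset, quiet_dataset.means) == 0.0

    def test_one_sigma_residual_is_one(self):
        ds = cf.TimeSeriesDataset(
            np.arange(4.0), np.zeros((2, 4)), np.full((2, 4), 0.3)
        )
        pred = np.zeros((2, 4))
        pred[1, 2] = 0.3
        assert cf.cost(ds, pred) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_double_loop_oracle(self, data):
        draw = data.draw
        means = np.array(draw(st.lists(
            st.lists(st.floats(-5, 5), min_size=4, max_size=4),
            min_size=3, max_size=3,
        )))
        pred = means + np.array(draw(st.lists(
            st.lists(st.floats(-1, 1), min_size=4, max_size=4),
            min_size=3, max_size=3,
        )))
        ds = cf.TimeSeriesDataset(np.arange(4.0), means, np.full((3, 4), 0.7))
        brute = 0.0
        for i in range(3):
            for j in range(4):
                brute += (means[i, j] - pred[i, j]) ** 2 / 0.7**2
        assert cf.cost(ds, pred) == pytest.approx(brute, abs=1e-12, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(cf.ArgumentError):
            cf.TimeSeriesDataset(np.arange(4.0), np.zeros((1, 4)), np.zeros((1, 4)))


class TestBuildInitialGuess:
    def test_guess_length_includes_period(self, goodwin, quiet_dataset):
        config = cf.CollocationConfig(n_elements=12, degree=4)
        guess = cf.build_initial_guess(quiet_dataset, goodwin, config)
        assert guess.size == cf.count_decision_variables(12, 4, 3, 6) + 1

    def test_guess_has_low_initial_cost(self, goodwin, quiet_dataset):
        config = cf.CollocationConfig()
        guess = cf.build_initial_guess(quiet_dataset, goodwin, config)
        pred = _collocation_prediction(goodwin, config, guess, quiet_dataset.times)
        assert cf.cost(quiet_dataset, pred) < 1e-2 * quiet_dataset.n_samples * goodwin.neq

    def test_interpolant_reproduces_smooth_data(self, goodwin, quiet_dataset):
        config = cf.CollocationConfig()
        guess = cf.build_initial_guess(quiet_dataset, goodwin, config)
        pred = _collocation_prediction(goodwin, config, guess, quiet_dataset.times)
        amp = quiet_dataset.means.max(axis=1) - quiet_dataset.means.min(axis=1)
        rel = np.abs(pred - quiet_dataset.means) / amp[:, None]
        assert np.max(rel) < 0.01

    def test_unmeasured_state_rejected(self, goodwin, quiet_dataset):
        means = quiet_dataset.means.copy()
        means[1, :] = np.nan
        ds = cf.TimeSeriesDataset(
            quiet_dataset.times, means, quiet_dataset.stds, quiet_dataset.state_names
        )
        with pytest.raises(cf.ArgumentError, match="x2"):
            cf.build_initial_guess(ds, goodwin, cf.CollocationConfig())


def _collocation_prediction(model, config, guess, times):
    """Evaluate the piecewise collocation polynomial of a decision vector."""
    basis = cf.collocation_points(config.degree, config.scheme)
    n_el, k1, neq = config.n_elements, config.degree + 1, model.neq
    X = guess[: n_el * k1 * neq].reshape(n_el, k1, neq)
    T = guess[-1]
    pred = np.empty((neq, times.size))
    for j, t in enumerate(times):
        tau = (t / T) % 1.0
        e = min(int(tau * n_el), n_el - 1)
        s = tau * n_el - e
        pred[:, j] = basis.values(s) @ X[e]
    return pred


class TestEstimateParameters:
    def test_noise_free_optimum_cost_below_guess_cost(self, goodwin, quiet_dataset):
        res = cf.estimate_parameters(goodwin, quiet_dataset)
        assert res.status == "converged"
        assert res.cost <= res.guess_cost

    def test_collocation_consistent_with_integration(self, goodwin, quiet_dataset):
        res = cf.estimate_parameters(goodwin, quiet_dataset)
        assert res.traj_discrepancy <= 1e-4

    def test_refinement_convergence(self, goodwin, quiet_dataset):
        coarse = cf.estimate_parameters(
            goodwin, quiet_dataset, cf.CollocationConfig(n_elements=12)
        )
        fine = cf.estimate_parameters(
            goodwin, quiet_dataset, cf.CollocationConfig(n_elements=24)
        )
        assert np.max(np.abs(fine.p_star / coarse.p_star - 1.0)) < 1e-3

    def test_weight_equivariance(self, goodwin, quiet_dataset):
        scale = 3.0
        scaled = cf.TimeSeriesDataset(
            quiet_dataset.times, quiet_dataset.means,
            scale * quiet_dataset.stds, quiet_dataset.state_names,
        )
        base = cf.estimate_parameters(goodwin, quiet_dataset)
        res = cf.estimate_parameters(goodwin, scaled)
        assert res.cost == pytest.approx(base.cost / scale**2, rel=1e-3, abs=1e-10)
        np.testing.assert_allclose(res.p_star, base.p_star, rtol=1e-3)

    def test_chi_square_scale_of_noisy_fits(self, goodwin, truth30):
        # with correct weights the optimal cost is of order the residual count
        noise = cf.NoiseModel(xi=0.05, eta=0.001)
        n_resid = truth30.n_samples * goodwin.neq
        rng_seeds = range(20)
        costs = []
        for seed in rng_seeds:
            ds = cf.generate_bootstrap_dataset(truth30, noise, seed)
            res = cf.estimate_parameters(goodwin, ds)
            assert res.status == "converged"
            costs.append(res.cost)
        costs = np.array(costs)
        assert np.all(costs > 0.2 * n_resid)
        assert np.all(costs < 5.0 * n_resid)

    def test_missing_single_points_are_dropped(self, goodwin, quiet_dataset):
        means = quiet_dataset.means.copy()
        means[0, 3] = np.nan
        means[2, 17] = np.nan
        ds = cf.TimeSeriesDataset(
            quiet_dataset.times, means, quiet_dataset.stds, quiet_dataset.state_names
        )
        res = cf.estimate_parameters(goodwin, ds)
        assert res.status == "converged"
        assert np.max(np.abs(res.p_star / goodwin.nominal_params - 1.0)) < 0.02

    def test_period_recovered(self, goodwin, quiet_dataset):
        res = cf.estimate_parameters(goodwin, quiet_dataset)
        assert res.period == pytest.approx(GOODWIN_PERIOD, rel=1e-3)
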