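"""The stacking meta-model: transform, likelihoods, constrained fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import poisson

from conftest import random_counts, random_simplex
from vgscmap.metamodel import (
    MultinomialStacking,
    class_probabilities,
    empirical_logit,
    inverse_empirical_logit,
    linear_predictor,
    multinomial_loglik,
    poisson_loglik,
    profile_intercepts,
)


class TestEmpiricalLogit:
    def test_half_maps_to_zero_for_any_eps(self):
        for eps in (1e-4, 1e-3, 0.1):
            assert empirical_logit(0.5, eps) == pytest.approx(0.0, abs=1e-15)

    def test_boundary_value_matches_formula(self):
        assert empirical_logit(0.0, 1e-3) == pytest.approx(
            np.log(0.001 / 1.001), abs=1e-12
        )
        assert np.isfinite(empirical_logit(1.0, 1e-3))

    def test_antisymmetry_on_grid(self):
        p = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            empirical_logit(p), -empirical_logit(1 - p), atol=1e-12
        )

    def test_strictly_increasing_and_invertible(self):
        p = np.linspace(0, 1, 101)
        x = empirical_logit(p)
        assert (np.diff(x) > 0).all()
        np.testing.assert_allclose(inverse_empirical_logit(x), p, atol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            empirical_logit(1.2)
        with pytest.raises(ValueError):
            empirical_logit(0.5, eps=0.0)


class TestLinearPredictor:
    def test_zero_coefficients_give_zero(self, rng):
        X = rng.normal(size=(3, 5, 3))
        np.testing.assert_array_equal(
            linear_predictor(np.zeros((3, 3)), X), np.zeros((5, 3))
        )

    def test_single_learner_passthrough(self, rng):
        X = rng.normal(size=(3, 5, 3))
        B = np.zeros((3, 3))
        B[0] = 1.0
        np.testing.assert_allclose(linear_predictor(B, X), X[0])

    def test_hand_summed_on_unit_inputs(self):
        B = np.array([[0.5, 0.5, 0.5], [0.3, 0.3, 0.3], [0.2, 0.2, 0.2]])
        X = np.ones((3, 4, 3))
        np.testing.assert_allclose(linear_predictor(B, X), 1.0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            linear_predictor(np.zeros((2, 3)), rng.normal(size=(3, 5, 3)))


class TestClassProbabilities:
    def test_uniform_at_zero(self):
        np.testing.assert_allclose(
            class_probabilities(np.zeros((1, 3)))[0], [1 / 3] * 3, atol=1e-15
        )

    def test_shift_invariance(self, rng):
        V = rng.normal(size=(6, 3))
        shifted = V + rng.normal(size=(6, 1))
        np.testing.assert_allclose(
            class_probabilities(V), class_probabilities(shifted), atol=1e-12
        )

    def test_hand_computed_exponentials(self):
        V = np.log([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(
            class_probabilities(V)[0], [1 / 6, 2 / 6, 3 / 6], atol=1e-12
        )

    def test_no_overflow_for_large_predictor(self):
        p = class_probabilities(np.array([[1000.0, 999.0, 0.0]]))
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestPoissonLikelihood:
    def test_matches_independent_density_sum(self, rng):
        """Value agrees with scipy's Poisson log-pmf summed over (i, j)."""
        Q, N, J = 3, 5, 3
        X = rng.normal(size=(Q, N, J))
        B = rng.uniform(0, 1, size=(Q, J))
        phi = rng.normal(size=N)
        Y = rng.poisson(5.0, size=(N, J)).astype(float)
        rates = np.exp(linear_predictor(B, X) + phi[:, None])
        expected = poisson.logpmf(Y, rates).sum()
        got = poisson_loglik(Y, B, phi, X, include_constant=True)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_counts_reduce_to_rate_sum(self, rng):
        X = rng.normal(size=(2, 4, 3))
        B = rng.uniform(size=(2, 3))
        phi = rng.normal(size=4)
        rates = np.exp(linear_predictor(B, X) + phi[:, None])
        assert poisson_loglik(np.zeros((4, 3)), B, phi, X) == pytest.approx(
            -rates.sum(), abs=1e-10
        )

    def test_single_cell_collapses_to_poisson_density(self, rng):
        X = rng.normal(size=(1, 1, 1))
        B = np.array([[0.7]])
        phi = np.array([0.3])
        y = np.array([[4.0]])
        rate = np.exp(0.7 * X[0, 0, 0] + 0.3)
        assert poisson_loglik(y, B, phi, X, include_constant=True) == pytest.approx(
            poisson.logpmf(4, rate), abs=1e-12
        )


class TestProfileIntercepts:
    def test_closed_form_at_zero_coefficients(self, rng):
        Y = random_counts(rng, random_simplex(rng, 6, 3))
        X = rng.normal(size=(3, 6, 3))
        phi = profile_intercepts(Y, np.zeros((3, 3)), X)
        np.testing.assert_allclose(phi, np.log(Y.sum(axis=1) / 3), atol=1e-12)

    def test_stationarity_of_poisson_loglik_in_phi(self, rng):
        Y = random_counts(rng, random_simplex(rng, 5, 3)).astype(float)
        X = rng.normal(size=(3, 5, 3))
        B = rng.uniform(size=(3, 3))
        phi = profile_intercepts(Y, B, X)
        # analytic gradient in phi_i: n_i - sum_j rate_ij = 0 at the profile
        rates = np.exp(linear_predictor(B, X) + phi[:, None])
        np.testing.assert_allclose(
            Y.sum(axis=1) - rates.sum(axis=1), 0.0, atol=1e-10
        )

    def test_transformation_equivalence_constant_in_B(self, rng):
        """Profiled Poisson and multinomial log-likelihoods differ by a
        B-free constant: the multinomial-Poisson identity."""
        for _ in range(10):
            N, J = 8, 3
            Y = random_counts(rng, random_simplex(rng, N, J)).astype(float)
            X = rng.normal(size=(3, N, J))
            diffs = []
            for _ in range(4):
                B = rng.uniform(0, 2, size=(3, J))
                prof = poisson_loglik(Y, B, profile_intercepts(Y, B, X), X)
                diffs.append(prof - multinomial_loglik(Y, B, X))
            assert np.ptp(diffs) < 1e-8


def simulate_from_model(rng, N, depth=40, informative=0):
    """Counts drawn from the meta-model itself with B* = passthrough of
    one learner; returns (counts, frequency matrices, true probabilities)."""
    truth = random_simplex(rng, N, 3)
    x1 = truth
    x2 = random_simplex(rng, N, 3)
    x3 = random_simplex(rng, N, 3)
    B_star = np.zeros((3, 3))
    B_star[0] = 1.0
    X = empirical_logit(np.stack([x1, x2, x3]))
    p = class_probabilities(linear_predictor(B_star, X))
    Y = np.vstack([rng.multinomial(depth, row) for row in p])
    return Y, [x1, x2, x3], p


class TestFit:
    def test_planted_signal_dominates_coefficients(self, rng):
        N = 2000
        freq = random_simplex(rng, N, 3)
        Y = random_counts(rng, freq)
        obs_freq = Y / Y.sum(axis=1, keepdims=True)
        mats = [obs_freq, random_simplex(rng, N, 3), random_simplex(rng, N, 3)]
        fit = MultinomialStacking(Y, mats).fit()
        B = fit.B
        assert B[0].sum() / B.sum() > 0.8

    def test_probability_recovery_from_own_model(self, rng):
        Y, mats, p_true = simulate_from_model(rng, 2000)
        fit = MultinomialStacking(Y, mats).fit()
        mad = np.abs(fit.fittedvalues.to_numpy() - p_true).mean()
        assert mad < 0.02

    def test_dual_objective_equivalence(self, rng):
        """Constrained optimum of the profiled Poisson objective matches a
        direct constrained maximisation of the multinomial likelihood."""
        Y, mats, _ = simulate_from_model(rng, 120)
        model = MultinomialStacking(Y, mats)
        fit = model.fit()
        X = model.X

        def neg_multinomial(b):
            return -multinomial_loglik(Y, b.reshape(3, 3), X)

        direct = minimize(
            neg_multinomial,
            np.full(9, 0.5),
            method="L-BFGS-B",
            bounds=[(0.0, None)] * 9,
            options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 2000},
        )
        p_direct = class_probabilities(
            linear_predictor(direct.x.reshape(3, 3), X)
        )
        np.testing.assert_allclose(
            fit.fittedvalues.to_numpy(), p_direct, atol=1e-4
        )

    def test_all_coefficients_nonnegative_exactly(self, rng):
        Y, mats, _ = simulate_from_model(rng, 150)
        fit = MultinomialStacking(Y, mats).fit()
        assert (fit.B >= 0).all()

    def test_deterministic_given_start(self, rng):
        Y, mats, _ = simulate_from_model(rng, 100)
        f1 = MultinomialStacking(Y, mats).fit()
        f2 = MultinomialStacking(Y, mats).fit()
        np.testing.assert_array_equal(f1.B, f2.B)

    def test_counts_validation(self, rng):
        mats = [random_simplex(rng, 4, 3)] * 3
        with pytest.raises(ValueError, match="non-negative integers"):
            MultinomialStacking(np.array([[1.5, 0, 0]] * 4), mats)

    def test_summary_mentions_convergence_and_coefficients(self, rng):
        Y, mats, _ = simulate_from_model(rng, 80)
        fit = MultinomialStacking(Y, mats).fit()
        text = fit.summary()
        assert "converged: True" in text
        assert "beta" in text


class TestPredict:
    def test_passthrough_equals_softmax_of_learner_logits(self, rng):
        Y, mats, _ = simulate_from_model(rng, 100)
        model = MultinomialStacking(Y, mats)
        fit = model.fit()
        fit.B = np.zeros((3, 3))
        fit.B[0] = 1.0
        new = [random_simplex(rng, 20, 3) for _ in range(3)]
        got = fit.predict(new)
        logits = empirical_logit(new[0])
        np.testing.assert_allclose(got, class_probabilities(logits), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        Y, mats, _ = simulate_from_model(rng, 100)
        fit = MultinomialStacking(Y, mats).fit()
        p = fit.predict([random_simplex(rng, 50, 3) for _ in range(3)])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_binary_variant_matches_hand_coded_sigmoid(self, rng):
        """J = 2 runs the identical code path and collapses to logistic."""
        p2 = random_simplex(rng, 300, 2)
        Y = random_counts(rng, p2)
        mats = [p2, random_simplex(rng, 300, 2), random_simplex(rng, 300, 2)]
        fit = MultinomialStacking(Y, mats).fit()
        assert fit.B.shape == (3, 2)
        new = [random_simplex(rng, 10, 2) for _ in range(3)]
        got = fit.predict(new)
        X = empirical_logit(np.stack(new))
        V = np.einsum("qj,qnj->nj", fit.B, X)
        sigmoid = 1.0 / (1.0 + np.exp(-(V[:, 1] - V[:, 0])))
        np.testing.assert_allclose(got[:, 1], sigmoid, atol=1e-12)

    def test_json_round_trip(self, rng, tmp_path):
        Y, mats, _ = simulate_from_model(rng, 60)
        fit = MultinomialStacking(Y, mats).fit()
        path = tmp_path / "metafit.json"
        fit.to_json(path)
        from vgscmap.metamodel import MultinomialStackingResults

        B, eps = MultinomialStackingResults.load_coefficients(path)
        np.testing.assert_allclose(B.to_numpy(), fit.B)
        assert eps == fit.model.eps


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_property_fitted_probabilities_on_simplex(seed):
    rng = np.random.default_rng(seed)
    Y, mats, _ = simulate_from_model(rng, 40)
    fit = MultinomialStacking(Y, mats).fit()
    p = fit.fittedvalues.to_numpy()
    assert ((p >= 0) & (p <= 1)).all()
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
    assert (fit.B >= 0).all()
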