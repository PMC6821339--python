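"""Index-weight constructions checked against hand algebra and an
independent constrained-optimization oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gainsel import (
    GeneticParameters,
    TraitPanel,
    correlated_responses,
    desired_gain_weights_full,
    implied_economic_values,
    index_sd_and_intensity,
    normalize_economic_values,
    relative_change,
    restricted_gain_weights,
    score_index,
    smith_hazel_weights,
)
from gainsel.engine import SingularMatrixError, format_ratio

from conftest import random_psd_instance


def qp_oracle(params, Q, mask):
    """argmin b' P b subject to (G[:, mask])' b = Q, via SLSQP.

    Deliberately avoids the closed-form linear algebra so it can serve as
    an independent check of the restricted-index construction.
    """
    n = params.n
    G_star = params.G[:, mask]
    res = minimize(
        lambda b: b @ params.P @ b,
        x0=np.zeros(n),
        jac=lambda b: 2 * params.P @ b,
        constraints=[{"type": "eq",
                      "fun": lambda b: G_star.T @ b - Q,
                      "jac": lambda b: G_star.T}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    assert res.success, res.message
    return res.x


class TestScoreIndex:
    def test_examples(self):
        assert score_index([1.0, 0.0], [3.2, 99.0]) == 3.2
        assert score_index([0.0, 0.0], [5.0, -7.0]) == 0.0
        assert score_index([0.4, 0.2], [1.0, 1.0]) == pytest.approx(0.6)

    def test_rowwise_on_population(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(score_index([1.0, -1.0], X), [-1.0, -1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            score_index([1.0], [1.0, 2.0])


class TestSmithHazel:
    def test_identity_and_univariate(self, identity2):
        np.testing.assert_allclose(smith_hazel_weights(identity2, [1.0, 0.0]), [1.0, 0.0])
        uni = GeneticParameters(G=[[0.5]], P=[[1.0]])
        # univariate index weight is h^2 times the economic value
        np.testing.assert_allclose(smith_hazel_weights(uni, [1.0]), [0.5])

    def test_two_trait_solve(self, params2):
        np.testing.assert_allclose(
            smith_hazel_weights(params2, [1.0, 1.0]), [0.4, 0.2], atol=1e-12
        )

    def test_singular_P_rejected(self):
        params = GeneticParameters(G=np.eye(2), P=np.ones((2, 2)))
        with pytest.raises(SingularMatrixError, match="P"):
            smith_hazel_weights(params, [1.0, 0.0])


class TestDesiredGainWeights:
    def test_identity_and_scalar(self, identity2):
        np.testing.assert_allclose(
            desired_gain_weights_full(identity2, [2.0, -1.0]), [2.0, -1.0]
        )
        uni = GeneticParameters(G=[[0.25]], P=[[1.0]])
        np.testing.assert_allclose(desired_gain_weights_full(uni, [0.5]), [2.0])

    def test_restricted_identity_case(self, identity2):
        b = restricted_gain_weights(identity2, [2.0], np.array([0]))
        np.testing.assert_allclose(b, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(correlated_responses(identity2, b), [2.0, 0.0])
        sigma, i = index_sd_and_intensity(identity2, b)
        assert sigma == pytest.approx(2.0)

    def test_restricted_two_trait_hand_case(self, params2):
        b = restricted_gain_weights(params2, [0.4], np.array([0]))
        np.testing.assert_allclose(b, [1.07692, -0.30769], atol=1e-5)
        assert correlated_responses(params2, b)[0] == pytest.approx(0.4, abs=1e-10)

    def test_degenerate_constraints_reported(self):
        # two constrained traits with identical genetic covariance columns
        G = np.ones((2, 2))
        params = GeneticParameters(G=G, P=G + np.eye(2))
        with pytest.raises(SingularMatrixError, match="unattainable|singular"):
            restricted_gain_weights(params, [1.0, 2.0], np.array([0, 1]))


@pytest.mark.parametrize("seed", range(20))
def test_restricted_weights_match_qp_oracle(seed):
    """The restricted index is the minimum-variance index hitting Q."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    params, Q, mask = random_psd_instance(rng, n, m=int(rng.integers(1, n)))
    b = restricted_gain_weights(params, Q, mask)
    b_oracle = qp_oracle(params, Q, mask)
    np.testing.assert_allclose(b, b_oracle, atol=1e-6)


@pytest.mark.parametrize("seed", range(100))
def test_gain_achievement_invariant(seed):
    """(G b) on the constrained traits equals Q for any valid instance."""
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(2, 10))
    params, Q, mask = random_psd_instance(rng, n)
    b = restricted_gain_weights(params, Q, mask)
    achieved = correlated_responses(params, b)[mask]
    np.testing.assert_allclose(achieved, Q, rtol=1e-8, atol=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_full_constraint_reduces_to_direct_solve(seed):
    """With every trait constrained, the restricted index is G^-1 Q."""
    rng = np.random.default_rng(2000 + seed)
    n = int(rng.integers(2, 8))
    params, Q, _ = random_psd_instance(rng, n, m=n)
    Q = rng.normal(size=n)
    np.testing.assert_allclose(
        restricted_gain_weights(params, Q, np.arange(n)),
        desired_gain_weights_full(params, Q),
        rtol=1e-8, atol=1e-10,
    )


@pytest.mark.parametrize("seed", range(10))
def test_economic_value_weight_duality(seed):
    """b -> a -> b and a -> b -> a are identities for invertible G, P."""
    rng = np.random.default_rng(3000 + seed)
    n = int(rng.integers(2, 8))
    params, _, _ = random_psd_instance(rng, n)
    b = rng.normal(size=n)
    np.testing.assert_allclose(
        smith_hazel_weights(params, implied_economic_values(params, b)), b,
        rtol=1e-8, atol=1e-10,
    )
    a = rng.normal(size=n)
    np.testing.assert_allclose(
        implied_economic_values(params, smith_hazel_weights(params, a)), a,
        rtol=1e-8, atol=1e-10,
    )


@pytest.mark.parametrize("seed, c", [(0, 2.5), (1, -3.0), (2, 0.1)])
def test_scale_equivariance_and_sd_homogeneity(seed, c):
    rng = np.random.default_rng(4000 + seed)
    params, _, _ = random_psd_instance(rng, 4)
    a = rng.normal(size=4)
    b = smith_hazel_weights(params, a)
    np.testing.assert_allclose(smith_hazel_weights(params, c * a), c * b, rtol=1e-9)
    sigma, _ = index_sd_and_intensity(params, b)
    sigma_c, _ = index_sd_and_intensity(params, c * b)
    assert sigma_c == pytest.approx(abs(c) * sigma, rel=1e-10)
    # ranking of a population is invariant to positive rescaling
    X = rng.normal(size=(30, 4))
    if c > 0:
        assert np.array_equal(np.argsort(score_index(b, X)),
                              np.argsort(score_index(c * b, X)))


class TestEconomicValues:
    def test_G_equals_P_cancels(self):
        G = np.array([[2.0, 0.3], [0.3, 1.0]])
        params = GeneticParameters(G=G, P=G)
        b = np.array([0.7, -1.2])
        np.testing.assert_allclose(implied_economic_values(params, b), b, rtol=1e-10)

    def test_normalization_and_scale_invariance(self):
        np.testing.assert_allclose(
            normalize_economic_values(np.array([4.4, 2.0]), 1), [2.2, 1.0]
        )
        a = np.array([3.0, -1.5, 0.5])
        np.testing.assert_allclose(
            normalize_economic_values(a, 2), normalize_economic_values(-7.0 * a, 2)
        )
        with pytest.raises(ZeroDivisionError):
            normalize_economic_values(np.array([1.0, 0.0]), 1)

    def test_ratio_printing_convention(self):
        assert format_ratio(-180.4) == "-180"
        assert format_ratio(2.23) == "2.2"
        assert format_ratio(9.96) == "10.0"
        assert format_ratio(10.4) == "10"


class TestResponsesAndIntensity:
    def test_correlated_response_trivial_cases(self, identity2, params2):
        np.testing.assert_array_equal(
            correlated_responses(params2, np.zeros(2)), np.zeros(2)
        )
        b = np.array([0.3, -0.6])
        np.testing.assert_array_equal(correlated_responses(identity2, b), b)

    def test_sigma_is_euclidean_norm_under_identity_P(self):
        params = GeneticParameters(G=0.5 * np.eye(2), P=np.eye(2))
        sigma, i = index_sd_and_intensity(params, np.array([3.0, 4.0]))
        assert sigma == i == pytest.approx(5.0)

    def test_univariate_breeders_equation(self):
        """i = R / (h^2 sigma_P): one trait, h^2 = 0.25, sigma_P = 1, R = 0.5."""
        params = GeneticParameters(G=[[0.25]], P=[[1.0]])
        b = desired_gain_weights_full(params, [0.5])
        np.testing.assert_allclose(b, [2.0])
        sigma, i = index_sd_and_intensity(params, b)
        assert i == pytest.approx(0.5 / (0.25 * 1.0))

    def test_zero_weights_give_zero_sigma(self, params2):
        sigma, _ = index_sd_and_intensity(params2, np.zeros(2))
        assert sigma == 0.0

    def test_relative_change(self):
        panel = TraitPanel(["A", "B"], ["d", "g"], [221.21, 1065.47], reference="B")
        pct = relative_change(np.array([44.0, 213.0]), panel)
        assert round(pct[0], 1) == 19.9
        assert round(pct[1], 1) == 20.0
        np.testing.assert_allclose(relative_change(np.zeros(2), panel), [0.0, 0.0])
        bad = TraitPanel(["A"], ["d"], [0.0], reference="A")
        with pytest.raises(ZeroDivisionError):
            relative_change(np.array([1.0]), bad)

    def test_ill_conditioned_matrix_warns(self):
        P = np.diag([1.0, 1e-14])
        params = GeneticParameters(G=0.5 * P, P=P)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            smith_hazel_weights(params, np.array([1.0, 1.0]))
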