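"""Core types, the dense GLS oracle, and scan-level statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lmmscan import (
    DimensionError,
    DomainError,
    FactorizationError,
    KinshipMatrix,
    ResultCube,
    SingularDesignError,
    VarianceEstimate,
    bonferroni_threshold,
    build_covariance,
    gc_lambda,
    gls_solve,
    wald_test,
)
from lmmscan.model import CHI2_1_MEDIAN

from conftest import random_pd_matrix


class TestDomainTypes:
    def test_kinship_rejects_asymmetry_and_nonsquare(self):
        with pytest.raises(DomainError):
            KinshipMatrix(values=[[1.0, 0.4], [0.5, 1.0]], sample_ids=["a", "b"])
        with pytest.raises(DimensionError):
            KinshipMatrix(values=np.ones((2, 3)), sample_ids=["a", "b"])
        with pytest.raises(DomainError):
            KinshipMatrix(values=[[0.0, 0.0], [0.0, 1.0]], sample_ids=["a", "b"])

    def test_variance_estimate_domain(self):
        with pytest.raises(DomainError):
            VarianceEstimate(sigma2=-1.0, h2=0.5)
        with pytest.raises(DomainError):
            VarianceEstimate(sigma2=1.0, h2=1.0)
        ve = VarianceEstimate(sigma2=2.0, h2=0.0, n_iter=5)
        assert ve.n_iter == 5

    def test_result_cube_shape_consistency(self):
        with pytest.raises(DimensionError):
            ResultCube(B=np.zeros((2, 1, 3)), SE=np.zeros((2, 1, 2)),
                       CHI2=np.zeros((2, 1)), snp_ids=["a", "b"],
                       trait_ids=["t"], coef_names=["i", "c", "s"])


class TestBuildCovariance:
    def test_identity_kinship_collapses_mixture(self):
        M = build_covariance(np.eye(2), sigma2=2.0, h2=0.5)
        np.testing.assert_allclose(M.M, 2.0 * np.eye(2))

    def test_h2_zero_removes_kinship(self, rng):
        phi = random_pd_matrix(rng, 5)
        M = build_covariance(phi, sigma2=3.0, h2=0.0)
        np.testing.assert_allclose(M.M, 3.0 * np.eye(5))

    def test_elementwise_mixture(self):
        M = build_covariance(np.array([[1.0, 0.5], [0.5, 1.0]]), sigma2=1.0, h2=0.8)
        np.testing.assert_allclose(M.M, [[1.0, 0.4], [0.4, 1.0]], atol=1e-15)

    def test_domain_and_dimension_errors(self):
        with pytest.raises(DimensionError):
            build_covariance(np.ones((2, 3)), 1.0, 0.5)
        with pytest.raises(DomainError):
            build_covariance(np.eye(2), 1.0, 1.0)
        with pytest.raises(DomainError):
            build_covariance(np.eye(2), 0.0, 0.5)


class TestGlsSolve:
    def test_ols_mean(self):
        beta, _, _ = gls_solve(np.array([[1.0], [1.0]]), [2.0, 4.0], np.eye(2))
        np.testing.assert_allclose(beta, [3.0])

    def test_heteroscedastic_hand_value(self):
        # XᵀM⁻¹X = 1.25, XᵀM⁻¹y = 3, hence beta = 2.4
        beta, se, _ = gls_solve(np.array([[1.0], [1.0]]), [2.0, 4.0],
                                np.diag([1.0, 4.0]))
        np.testing.assert_allclose(beta, [2.4])
        np.testing.assert_allclose(se, [np.sqrt(1 / 1.25)])

    def test_matches_explicit_inverse_formula(self, rng):
        for _ in range(20):
            n, p = 5, 2
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            M = random_pd_matrix(rng, n)
            beta, se, cov = gls_solve(X, y, M)
            Minv = np.linalg.inv(M)
            ref = np.linalg.inv(X.T @ Minv @ X) @ (X.T @ Minv @ y)
            np.testing.assert_allclose(beta, ref, rtol=1e-10)
            np.testing.assert_allclose(
                cov, np.linalg.inv(X.T @ Minv @ X), rtol=1e-9
            )

    def test_identity_covariance_is_ols(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        beta, _, _ = gls_solve(X, y, np.eye(30))
        ref, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ref, rtol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
    def test_beta_invariant_under_covariance_scaling(self, seed, c):
        """sigma² cancels in the estimator; SEs scale by sqrt(c)."""
        r = np.random.default_rng(seed)
        X = r.standard_normal((12, 3))
        y = r.standard_normal(12)
        M = random_pd_matrix(r, 12)
        beta1, se1, _ = gls_solve(X, y, M)
        beta2, se2, _ = gls_solve(X, y, c * M)
        np.testing.assert_allclose(beta1, beta2, rtol=1e-8)
        np.testing.assert_allclose(se2, np.sqrt(c) * se1, rtol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cov_symmetric_psd(self, seed):
        r = np.random.default_rng(seed)
        X = r.standard_normal((15, 4))
        y = r.standard_normal(15)
        M = random_pd_matrix(r, 15)
        _, _, cov = gls_solve(X, y, M)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_rank_deficient_design_names_column(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 2] = 2.0 * X[:, 0]
        with pytest.raises(SingularDesignError) as err:
            gls_solve(X, rng.standard_normal(10), np.eye(10))
        assert err.value.column == 2

    def test_non_pd_covariance_fails(self, rng):
        M = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(FactorizationError):
            gls_solve(rng.standard_normal((3, 1)), rng.standard_normal(3), M)

    def test_residual_rescaling_flag(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        M = random_pd_matrix(rng, 20)
        _, se_fixed, _ = gls_solve(X, y, M)
        _, se_scaled, _ = gls_solve(X, y, M, rescale_residual=True)
        assert not np.allclose(se_fixed, se_scaled)


class TestWaldTest:
    def test_null_statistic(self):
        chi2, p = wald_test(0.0, 1.0)
        assert chi2 == 0.0 and p == 1.0

    def test_normal_chi2_correspondence(self):
        _, p = wald_test(1.96, 1.0)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_sign_symmetry(self):
        chi2_neg, p_neg = wald_test(-2.0, 1.0)
        chi2_pos, p_pos = wald_test(2.0, 1.0)
        assert chi2_neg == chi2_pos == 4.0
        assert p_neg == p_pos

    def test_degenerate_se(self):
        with pytest.raises(DomainError):
            wald_test(1.0, 0.0)


class TestGcLambda:
    def test_definitional_unit_lambda(self):
        assert gc_lambda([CHI2_1_MEDIAN] * 7) == pytest.approx(1.0)

    def test_null_chi2_draws_near_one(self):
        draws = stats.chi2.rvs(df=1, size=100_000,
                               random_state=np.random.default_rng(7))
        lam = gc_lambda(draws)
        assert abs(lam - 1.0) < 0.03
        # scale equivariance of the median
        assert gc_lambda(2.0 * draws) == pytest.approx(2.0 * lam)

    def test_errors(self):
        with pytest.raises(DomainError):
            gc_lambda([])
        with pytest.raises(DomainError):
            gc_lambda([0.5, -0.1])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n_tests,expected",
        [(5e-8, 107_144, 5e-8 / 107_144), (0.05, 1, 0.05), (0.05, 100, 5e-4)],
    )
    def test_threshold(self, alpha, n_tests, expected):
        assert bonferroni_threshold(alpha, n_tests) == pytest.approx(expected)

    def test_metabolome_wide_value_rounds_to_printed_figure(self):
        # 5e-8 spread over 107,144 traits: 4.7e-13 at two significant figures
        assert f"{bonferroni_threshold(5e-8, 107_144):.1e}" == "4.7e-13"

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(DomainError):
            bonferroni_threshold(1.5, 10)
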