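import numpy as np
import pytest
from scipy.stats import multivariate_normal

from idopnet.errors import FitError, NotPositiveDefiniteError
from idopnet.sad import (
    BlockCov,
    SADParams,
    block_cov,
    mvn_loglik,
    sad_loglik,
    sad_matrix,
    sad_mle,
)


class TestSadMatrix:
    def test_phi_zero_is_scaled_identity(self):
        np.testing.assert_array_equal(
            sad_matrix(SADParams(0.0, 2.5, 4)), 2.5 * np.eye(4)
        )

    def test_determinant_is_nu2_to_the_n(self):
        for phi in (-0.8, -0.3, 0.5, 0.9):
            for nu2 in (0.5, 1.0, 3.0):
                M = sad_matrix(SADParams(phi, nu2, 5))
                assert np.linalg.det(M) == pytest.approx(nu2**5, rel=1e-9)

    def test_positive_definite_across_parameters(self, rng):
        for _ in range(20):
            phi = rng.uniform(-0.95, 0.95)
            nu2 = rng.uniform(0.1, 4.0)
            M = sad_matrix(SADParams(phi, nu2, 8))
            assert np.linalg.eigvalsh(M).min() > 0

    def test_matches_monte_carlo_recursion(self):
        # simulate e_1 = eps_1, e_i = phi e_{i-1} + eps_i and compare covariances
        rng = np.random.default_rng(7)
        phi, nu2, n, reps = 0.6, 1.3, 5, 200_000
        eps = rng.normal(0.0, np.sqrt(nu2), size=(reps, n))
        e = np.empty_like(eps)
        e[:, 0] = eps[:, 0]
        for i in range(1, n):
            e[:, i] = phi * e[:, i - 1] + eps[:, i]
        emp = np.cov(e, rowvar=False)
        M = sad_matrix(SADParams(phi, nu2, n))
        np.testing.assert_allclose(emp, M, rtol=0.02, atol=0.02 * nu2)

    def test_invalid_phi(self):
        with pytest.raises(FitError, match="phi"):
            SADParams(1.0, 1.0, 3)


class TestSadLoglik:
    def test_standard_normal_at_zero(self):
        assert sad_loglik(np.zeros(2), SADParams(0.0, 1.0, 2)) == pytest.approx(
            -np.log(2 * np.pi)
        )

    def test_equals_dense_gaussian_oracle(self, rng):
        for _ in range(10):
            phi = rng.uniform(-0.9, 0.9)
            nu2 = rng.uniform(0.2, 3.0)
            p = SADParams(phi, nu2, 7)
            resid = rng.normal(size=7)
            dense = multivariate_normal(np.zeros(7), sad_matrix(p)).logpdf(resid)
            assert sad_loglik(resid, p) == pytest.approx(dense, abs=1e-8)

    def test_scaling_residual_and_variance_together(self, rng):
        p1 = SADParams(0.4, 1.0, 6)
        p2 = SADParams(0.4, 4.0, 6)
        r = rng.normal(size=6)
        dense1 = multivariate_normal(np.zeros(6), sad_matrix(p1)).logpdf(r)
        dense2 = multivariate_normal(np.zeros(6), sad_matrix(p2)).logpdf(2 * r)
        assert sad_loglik(r, p1) == pytest.approx(dense1, abs=1e-8)
        assert sad_loglik(2 * r, p2) == pytest.approx(dense2, abs=1e-8)
        assert sad_loglik(2 * r, p2) - sad_loglik(r, p1) == pytest.approx(
            -6 * np.log(2), abs=1e-8
        )

    def test_mle_recovers_parameters(self):
        rng = np.random.default_rng(11)
        phi, nu2, n = 0.5, 1.5, 24
        eps = rng.normal(0, np.sqrt(nu2), size=(4000, n))
        e = np.empty_like(eps)
        e[:, 0] = eps[:, 0]
        for i in range(1, n):
            e[:, i] = phi * e[:, i - 1] + eps[:, i]
        est = sad_mle(e)
        assert est.phi == pytest.approx(phi, abs=0.02)
        assert est.nu2 == pytest.approx(nu2, rel=0.05)


class TestBlockCov:
    def test_zero_cross_correlation_is_block_diagonal(self):
        b = BlockCov(SADParams(0.3, 1.0, 4), SADParams(-0.2, 2.0, 4), 0.0)
        M = block_cov(b)
        np.testing.assert_array_equal(M[:4, 4:], np.zeros((4, 4)))
        np.testing.assert_allclose(M[:4, :4], sad_matrix(b.scion))
        np.testing.assert_allclose(M[4:, 4:], sad_matrix(b.rootstock))

    def test_moderate_rho_is_symmetric_pd(self):
        b = BlockCov(SADParams(0.5, 1.0, 4), SADParams(0.1, 0.5, 4), 0.3)
        M = block_cov(b)
        np.testing.assert_allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() > 0

    def test_swapping_blocks_transposes_cross(self):
        s, r = SADParams(0.5, 1.0, 3), SADParams(0.1, 0.5, 3)
        M1 = block_cov(BlockCov(s, r, 0.4))
        M2 = block_cov(BlockCov(r, s, 0.4))
        np.testing.assert_allclose(M1[:3, 3:], M2[3:, :3].T)

    def test_extreme_rho_rejected(self):
        with pytest.raises(FitError):
            BlockCov(SADParams(0.0, 1.0, 3), SADParams(0.0, 1.0, 3), 1.2)

    def test_mvn_loglik_matches_scipy(self, rng):
        b = BlockCov(SADParams(0.4, 1.2, 5), SADParams(-0.3, 0.8, 5), 0.25)
        M = block_cov(b)
        x = rng.normal(size=10)
        assert mvn_loglik(x, M) == pytest.approx(
            multivariate_normal(np.zeros(10), M).logpdf(x), abs=1e-8
        )
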