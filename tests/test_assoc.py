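"""Score tests, covariate residualization and the omnibus combination."""

import numpy as np
import pytest
from scipy import stats

from mlno.assoc import (
    estimate_sigma,
    mln_o_test,
    omnibus,
    residualize,
    score_test,
)


class TestResidualize:
    def test_no_covariates_centers(self, rng):
        T = rng.standard_normal((50, 3))
        R = residualize(T, None)
        assert np.allclose(R, T - T.mean(axis=0))

    def test_projection_idempotent(self, rng):
        Z = rng.standard_normal((80, 2))
        y = rng.standard_normal(80)
        r1 = residualize(y, Z)
        assert np.allclose(residualize(r1, Z), r1, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        T = rng.standard_normal((200, 3))
        Z = rng.standard_normal((200, 2))
        R = residualize(T, Z)
        X = np.column_stack([np.ones(200), Z])
        beta = np.linalg.solve(X.T @ X, X.T @ T)
        assert np.allclose(R, T - X @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        T = rng.standard_normal((100, 2))
        Z = rng.standard_normal((100, 3))
        R = residualize(T, Z)
        assert np.allclose(R.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.T @ R, 0.0, atol=1e-8)

    def test_rank_deficient_rejected(self, rng):
        Z = np.ones((30, 2))  # duplicates the intercept
        with pytest.raises(np.linalg.LinAlgError):
            residualize(rng.standard_normal(30), Z)


class TestScoreTest:
    def test_perfect_dependence(self, rng):
        x = rng.integers(0, 3, 40).astype(float)
        assert score_test(x, x) == pytest.approx(np.sqrt(40))

    def test_orthogonal_gives_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert score_test(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        x = np.array([0, 1, 2, 1], dtype=float)
        y = np.array([0, 0, 1, 1], dtype=float)
        expected = 2.0 * np.corrcoef(x, y)[0, 1]  # sqrt(4) * Pearson r
        assert score_test(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            score_test(np.ones(10), np.arange(10.0))

    def test_null_distribution_standard_normal(self):
        # sqrt(n)*corr is approximately N(0,1) under independence
        rng = np.random.default_rng(5)
        stats_ = []
        for _ in range(500):
            x = rng.binomial(2, 0.3, 2000).astype(float)
            y = (rng.random(2000) < 0.05).astype(float)
            stats_.append(score_test(x, y))
        assert abs(np.mean(stats_)) < 0.15
        assert abs(np.std(stats_) - 1.0) < 0.12


class TestSigma:
    def test_single_cluster(self, rng):
        M = rng.integers(0, 2, (30, 1)).astype(float)
        M[0] = 1 - M[0] if M.std() == 0 else M[0]
        assert np.array_equal(estimate_sigma(M), [[1.0]])

    def test_identical_columns_offdiag_one(self, rng):
        col = rng.integers(0, 2, 40).astype(float)
        col[:5] = 1; col[5:] = 0
        M = np.column_stack([col, col])
        sigma = estimate_sigma(M)
        assert sigma[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_pearson(self, rng):
        M = rng.standard_normal((100, 3))
        sigma = estimate_sigma(M)
        for j in range(3):
            for k in range(3):
                assert sigma[j, k] == pytest.approx(stats.pearsonr(M[:, j], M[:, k])[0])

    def test_zero_variance_rejected(self):
        M = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError):
            estimate_sigma(M)


class TestOmnibus:
    def test_single_statistic_chi1(self):
        res = omnibus(np.array([2.0]), np.array([[1.0]]))
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-6)
        assert res.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_identity_sigma_sum_of_squares(self, rng):
        T = rng.standard_normal(4)
        res = omnibus(T, np.eye(4))
        assert res.statistic == pytest.approx(float(T @ T))

    def test_closed_form_2x2(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = omnibus(np.array([1.0, 1.0]), sigma)
        assert res.statistic == pytest.approx(4.0 / 3.0)

    def test_cluster_order_invariance(self, rng):
        T = rng.standard_normal(3)
        sigma = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        perm = np.array([2, 0, 1])
        r1 = omnibus(T, sigma)
        r2 = omnibus(T[perm], sigma[np.ix_(perm, perm)])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_sign_flip_invariance(self, rng):
        T = rng.standard_normal(3)
        sigma = np.eye(3) * 0.7 + 0.3
        flip = np.diag([1.0, -1.0, 1.0])
        r1 = omnibus(T, sigma)
        r2 = omnibus(flip @ T, flip @ sigma @ flip)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_singular_sigma_guarded(self):
        sigma = np.ones((2, 2))
        with pytest.warns(UserWarning, match="near-singular"):
            res = omnibus(np.array([1.0, 1.0]), sigma)
        assert res.statistic >= 0
        assert 0 <= res.p_value <= 1


class TestPipeline:
    @staticmethod
    def _dataset(rng, n=800, K=4, r=0.05):
        from mlno.simulate import dichotomize, simulate_genotypes

        x = simulate_genotypes(n, 0.3, rng)
        Y = dichotomize(rng.standard_normal((n, K)), r)
        return x, Y

    def test_one_cluster_reduces_to_squared_score(self, rng):
        # phenotypes so entangled they form one cluster
        n = 500
        x = rng.binomial(2, 0.3, n).astype(float)
        base = (rng.random(n) < 0.1).astype(np.int8)
        Y = np.column_stack([base, base | (rng.random(n) < 0.02), base])
        res = mln_o_test(x, Y)
        assert res.df == 1
        merged = Y.max(axis=1).astype(float)
        t = score_test(x, merged)
        assert res.statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(stats.chi2.sf(t**2, 1))

    def test_duplicate_columns_match_deduplicated(self, rng):
        # under the literal (self-loop) modularity the duplicated pairs
        # merge and the result equals the de-duplicated run; the default
        # scoring cannot split a 2-phenotype network, so the literal
        # convention is the one where this invariance is well-posed
        n = 2000
        x = rng.binomial(2, 0.3, n).astype(float)
        a = (rng.random(n) < 0.05).astype(np.int8)
        b = (rng.random(n) < 0.05).astype(np.int8)
        r4 = mln_o_test(x, np.column_stack([a, a, b, b]), include_self_loops=True)
        r2 = mln_o_test(x, np.column_stack([a, b]), include_self_loops=True)
        assert r4.df == r2.df == 2
        assert r4.statistic == pytest.approx(r2.statistic)
        assert r4.p_value == pytest.approx(r2.p_value)

    def test_statistic_nonnegative_and_p_valid(self, rng):
        x, Y = self._dataset(rng)
        res = mln_o_test(x, Y)
        assert res.statistic >= 0
        assert 0 <= res.p_value <= 1
        assert res.sigma.shape == (res.df, res.df)

    def test_covariates_residualize_equivalence(self, rng):
        # running on pre-residualized data equals the covariate path
        x, Y = self._dataset(rng)
        Z = rng.standard_normal((x.shape[0], 2))
        res_cov = mln_o_test(x, Y, covariates=Z)
        asg = res_cov.assignment
        from mlno.community import merge_phenotypes

        merged = residualize(merge_phenotypes(Y, asg).astype(float), Z)
        xr = residualize(x.astype(float), Z)
        T = np.array([score_test(xr, merged[:, l]) for l in range(merged.shape[1])])
        res_manual = omnibus(T, estimate_sigma(merged))
        assert res_cov.statistic == pytest.approx(res_manual.statistic)

    def test_deterministic(self, rng):
        x, Y = self._dataset(rng)
        r1 = mln_o_test(x, Y)
        r2 = mln_o_test(x, Y)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value
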