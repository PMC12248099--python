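"""Two-sample statistics against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from fabgene import (
    DegenerateInputError,
    InsufficientReplicationError,
    SpikedPrior,
    TwoSampleData,
    afab_pvalue,
    afab_test,
    difference_of_means,
    oracle_null_quantile,
    pooled_covariance,
    rp_test,
    shrinkage_sigma_tilde,
    t_afab,
    t_fab_oracle,
    t_fab_quadratic,
    t_lfab,
)
from fabgene.simulate import make_covariance, make_embedding_basis, simulate_two_sample


def _random_spd(rng, p, scale=1.0):
    A = rng.standard_normal((p, p))
    return scale * (A @ A.T / p + np.eye(p))


class TestSufficientStatistics:
    def test_identical_samples_zero_difference(self, rng):
        x = rng.standard_normal((4, 3))
        y, eta = difference_of_means(TwoSampleData(x, x.copy()))
        np.testing.assert_allclose(y, 0.0, atol=1e-14)
        assert eta == pytest.approx(0.5)

    def test_eta_formula(self, rng):
        data = TwoSampleData(
            rng.standard_normal((50, 2)), rng.standard_normal((50, 2))
        )
        _, eta = difference_of_means(data)
        assert eta == pytest.approx(0.04)

    def test_mean_difference_loop_oracle(self, rng):
        data = TwoSampleData(
            rng.standard_normal((5, 4)), rng.standard_normal((7, 4))
        )
        y, _ = difference_of_means(data)
        for j in range(4):
            assert y[j] == pytest.approx(
                data.x1[:, j].mean() - data.x2[:, j].mean()
            )

    def test_pooled_covariance_scalar_oracle(self, rng):
        a = np.array([[1.0], [3.0]])
        b = np.array([[2.0], [6.0]])
        S = pooled_covariance(TwoSampleData(a, b))
        # ((1-2)^2+(3-2)^2 + (2-4)^2+(6-4)^2) / (2+2-2)
        assert S[0, 0] == pytest.approx((2.0 + 8.0) / 2.0)

    def test_pooled_covariance_constant_rows(self):
        data = TwoSampleData(np.ones((3, 2)), 2 * np.ones((2, 2)))
        np.testing.assert_allclose(pooled_covariance(data), 0.0, atol=1e-14)

    def test_pooled_covariance_psd(self, rng):
        data = TwoSampleData(
            rng.standard_normal((6, 5)), rng.standard_normal((4, 5))
        )
        S = pooled_covariance(data)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_insufficient_replication(self, rng):
        with pytest.raises(InsufficientReplicationError):
            pooled_covariance(
                TwoSampleData(rng.standard_normal((1, 2)), rng.standard_normal((1, 2)))
            )


class TestOracleStatistic:
    def test_vanishing_prior_gives_zero(self, rng):
        p = 4
        Sigma = _random_spd(rng, p)
        E = rng.standard_normal((p, 2))
        y = rng.standard_normal(p)
        stat = t_fab_oracle(y, Sigma, SpikedPrior(E, 1e-14, 1e-14), 0.1)
        assert abs(stat) < 1e-9

    def test_bivariate_closed_form(self, rng):
        # p=2 diagonal case: difference of two bivariate normal log densities
        Sigma = np.diag([2.0, 0.5])
        prior = SpikedPrior(np.array([[1.0], [0.0]]), 0.7, 0.3)
        eta, y = 0.25, np.array([0.8, -1.1])
        stat = t_fab_oracle(y, Sigma, prior, eta)
        null = stats.multivariate_normal(np.zeros(2), eta * Sigma)
        marg = stats.multivariate_normal(
            np.zeros(2), eta * Sigma + prior.cov()
        )
        assert stat == pytest.approx(marg.logpdf(y) - null.logpdf(y), rel=1e-10)

    def test_monotone_in_signal_norm(self, rng):
        p = 5
        E = rng.standard_normal((p, 2))
        prior = SpikedPrior(E, 1.0, 0.2)
        direction = rng.standard_normal(p)
        vals = [
            t_fab_oracle(c * direction, np.eye(p), prior, 0.1)
            for c in [0.5, 1.0, 2.0, 4.0]
        ]
        assert np.all(np.diff(vals) > 0)

    def test_quadratic_form_is_affine_in_oracle(self, rng):
        p = 6
        Sigma = _random_spd(rng, p)
        prior = SpikedPrior(rng.standard_normal((p, 2)), 0.8, 0.4)
        eta = 0.2
        ys = rng.standard_normal((8, p))
        log_lr = np.array([t_fab_oracle(y, Sigma, prior, eta) for y in ys])
        quad = np.array([t_fab_quadratic(y, Sigma, prior, eta) for y in ys])
        # log LR = quad / (2 eta) + constant
        shift = log_lr - quad / (2 * eta)
        np.testing.assert_allclose(shift, shift[0], rtol=1e-8)

    def test_woodbury_inverse(self, rng):
        prior = SpikedPrior(rng.standard_normal((7, 3)), 2.0, 0.5)
        np.testing.assert_allclose(
            prior.inv() @ prior.cov(), np.eye(7), atol=1e-10
        )


class TestOracleNull:
    def test_scalar_closed_form_quantile(self, rng):
        # p=1: the statistic is a monotone map of a scaled chi-square(1),
        # so the MC quantile must match the transformed inverse CDF
        sigma2, nu, gamma, eta = 1.5, 0.6, 0.2, 0.3
        Sigma = np.array([[sigma2]])
        prior = SpikedPrior(np.array([[1.0]]), nu, gamma)
        psi = nu + gamma
        alpha = 0.1
        q_mc = oracle_null_quantile(Sigma, prior, eta, alpha, 40000, 5)
        c = stats.chi2.ppf(1 - alpha, df=1)
        a, b = eta * sigma2, eta * sigma2 + psi
        expected = 0.5 * c * (1 / a - 1 / b) * a + 0.5 * np.log(a / b)
        assert q_mc == pytest.approx(expected, abs=0.05 * abs(expected) + 0.02)

    def test_level_self_consistency(self, rng):
        p, eta, alpha = 5, 0.2, 0.05
        Sigma = _random_spd(rng, p)
        prior = SpikedPrior(rng.standard_normal((p, 2)), 1.0, 0.3)
        q = oracle_null_quantile(Sigma, prior, eta, alpha, 20000, 7)
        L = np.linalg.cholesky(eta * Sigma)
        n_test = 5000
        hits = 0
        Y = rng.standard_normal((n_test, p)) @ L.T
        for y in Y:
            hits += t_fab_oracle(y, Sigma, prior, eta) > q
        rate = hits / n_test
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_test) + 0.005

    def test_alpha_near_one_gives_minimum(self, rng):
        p = 3
        Sigma = _random_spd(rng, p)
        prior = SpikedPrior(rng.standard_normal((p, 2)), 1.0, 0.3)
        q_low = oracle_null_quantile(Sigma, prior, 0.2, 0.9999, 500, 3)
        q_hi = oracle_null_quantile(Sigma, prior, 0.2, 0.05, 500, 3)
        assert q_low < q_hi

    def test_weighted_chisq_null_matches(self, rng):
        # the quadratic form's null is sum_j w_j chi2_1 with
        # w_j = eta / (eta lambda_j + 1), lambda_j eig of S^1/2 Psi^-1 S^1/2
        p, eta = 8, 0.2
        Sigma = _random_spd(rng, p)
        prior = SpikedPrior(rng.standard_normal((p, 3)), 1.0, 0.4)
        w_s, V_s = np.linalg.eigh(Sigma)
        root = V_s * np.sqrt(w_s) @ V_s.T
        lam = np.linalg.eigvalsh(root @ prior.inv() @ root)
        weights = eta / (eta * lam + 1.0)
        n = 3000
        chis = (rng.standard_normal((n, p)) ** 2) @ weights
        L = np.linalg.cholesky(eta * Sigma)
        Y = rng.standard_normal((n, p)) @ L.T
        quad = np.array([t_fab_quadratic(y, Sigma, prior, eta) for y in Y])
        assert stats.ks_2samp(chis, quad).pvalue > 0.01


class TestProjectionStatistics:
    def test_lfab_projection_identity(self, rng):
        p = 6
        Q, _ = np.linalg.qr(rng.standard_normal((p, 3)))
        y = rng.standard_normal(p)
        assert t_lfab(y, np.eye(p), Q) == pytest.approx(
            float(np.sum((Q.T @ y) ** 2))
        )

    def test_lfab_orthogonal_signal_is_zero(self, rng):
        p = 5
        Sigma = _random_spd(rng, p)
        E = rng.standard_normal((p, 2))
        A = np.linalg.solve(Sigma, E)
        # build y orthogonal to col(A)
        Q, _ = np.linalg.qr(A)
        y = rng.standard_normal(p)
        y -= Q @ (Q.T @ y)
        assert t_lfab(y, Sigma, E) == pytest.approx(0.0, abs=1e-18)

    def test_lfab_rank_deficient_error(self, rng):
        E = np.ones((5, 2))
        with pytest.raises(ValueError, match="rank"):
            t_lfab(rng.standard_normal(5), np.eye(5), E)

    @pytest.mark.parametrize("stat", ["lfab", "afab"])
    def test_invariance_under_column_recombination(self, rng, stat):
        p, d = 10, 3
        Sigma = _random_spd(rng, p)
        S = _random_spd(rng, p)
        E = rng.standard_normal((p, d))
        G = rng.standard_normal((d, d)) + 3 * np.eye(d)
        y = rng.standard_normal(p)
        if stat == "lfab":
            a = t_lfab(y, Sigma, E)
            b = t_lfab(y, Sigma, E @ G)
        else:
            a = t_afab(y, S, Sigma, E, 8, 9)
            b = t_afab(y, S, Sigma, E @ G, 8, 9)
        assert abs(a - b) / abs(a) < 1e-10

    def test_afab_identity_reduction(self, rng):
        p = 4
        Q, _ = np.linalg.qr(rng.standard_normal((p, 2)))
        y = rng.standard_normal(p)
        T = t_afab(y, np.eye(p), np.eye(p), Q, 6, 9)
        assert T == pytest.approx(6 * 9 / 15 * float(np.sum((Q.T @ y) ** 2)))

    def test_afab_full_dim_is_hotelling(self, rng):
        p, n1, n2 = 3, 10, 12
        data = TwoSampleData(
            rng.standard_normal((n1, p)), rng.standard_normal((n2, p))
        )
        y, _ = difference_of_means(data)
        S = pooled_covariance(data)
        T = t_afab(y, S, np.eye(p), np.eye(p), n1, n2)
        hotelling = (n1 * n2 / (n1 + n2)) * float(y @ np.linalg.solve(S, y))
        assert T == pytest.approx(hotelling, rel=1e-10)

    def test_afab_matrix_product_oracle(self, rng):
        p, d = 5, 2
        y = rng.standard_normal(p)
        S = _random_spd(rng, p)
        St = _random_spd(rng, p)
        E = rng.standard_normal((p, d))
        A = np.linalg.inv(St) @ E
        expected = (7 * 8 / 15) * float(
            y @ A @ np.linalg.inv(A.T @ S @ A) @ A.T @ y
        )
        assert t_afab(y, S, St, E, 7, 8) == pytest.approx(expected, rel=1e-8)

    def test_lfab_is_diffuse_limit_of_oracle(self, rng):
        # affine-map check: quadratic oracle at nu=1e8, gamma=1e-8 is an
        # affine function of T_LFAB (relative residual < 1e-3)
        p, d = 20, 4
        Sigma = _random_spd(rng, p)
        E = rng.standard_normal((p, d))
        prior = SpikedPrior(E, 1e8, 1e-8)
        eta = 0.1
        ys = rng.standard_normal((12, p))
        quad = np.array([t_fab_quadratic(y, Sigma, prior, eta) for y in ys])
        lfab = np.array([t_lfab(y, Sigma, E) for y in ys])
        a, b = np.polyfit(lfab, quad, 1)
        resid = quad - (a * lfab + b)
        assert np.abs(resid).max() / np.abs(quad).max() < 1e-3


class TestAfabPvalue:
    def test_zero_statistic(self):
        assert afab_pvalue(0.0, 10, 10, 3) == pytest.approx(1.0)

    def test_printed_scaling_inverts(self):
        # n1=n2=50, d=10: scaling constant 89/980; plugging the scaled
        # 95% F quantile back in must return p = 0.05
        n1 = n2 = 50
        d = 10
        q = stats.f.ppf(0.95, d, 89)
        T = q * 980.0 / 89.0
        assert afab_pvalue(T, n1, n2, d) == pytest.approx(0.05, rel=1e-10)

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            afab_pvalue(1.0, 3, 2, 5)


class TestAfabTest:
    def test_split_grid_accepted(self, rng):
        data = TwoSampleData(
            rng.standard_normal((50, 8)), rng.standard_normal((50, 8))
        )
        E = rng.standard_normal((8, 2))
        for r in (0.5, 0.66, 0.8):
            res = afab_test(data, E, "split_sample", r=r, seed=1)
            assert 0.0 <= res.p_value <= 1.0

    def test_split_r066_allocates_33_of_50(self, rng):
        # ceil(0.66 * 50) = 33 fit rows -> df_den = 66 - d - 1
        data = TwoSampleData(
            rng.standard_normal((50, 6)), rng.standard_normal((50, 6))
        )
        E = rng.standard_normal((6, 2))
        res = afab_test(data, E, "split_sample", r=0.66, seed=0)
        assert res.df_den == 66 - 2 - 1

    def test_split_infeasible_r(self, rng):
        data = TwoSampleData(
            rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        )
        with pytest.raises(ValueError):
            afab_test(data, rng.standard_normal((4, 2)), "split_sample", r=0.99)

    def test_single_treated_profile(self, rng):
        # n2=1: S from the control sample alone, effective total n1+1
        n1, p, d = 20, 10, 3
        data = TwoSampleData(
            rng.standard_normal((n1, p)), rng.standard_normal((1, p))
        )
        E = rng.standard_normal((p, d))
        res = afab_test(data, E, "naive")
        assert res.df_den == (n1 + 1) - d - 1
        assert 0.0 <= res.p_value <= 1.0

    def test_single_profile_null_calibration(self, rng):
        n1, p, d, reps, alpha = 15, 8, 2, 1000, 0.05
        E = rng.standard_normal((p, d))
        Sigma = _random_spd(rng, p)
        L = np.linalg.cholesky(Sigma)
        hits = 0
        for _ in range(reps):
            data = TwoSampleData(
                rng.standard_normal((n1, p)) @ L.T,
                rng.standard_normal((1, p)) @ L.T,
            )
            hits += afab_test(data, E, "naive").p_value <= alpha
        assert abs(hits / reps - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_seed_reproducibility(self, rng):
        data = TwoSampleData(
            rng.standard_normal((20, 6)), rng.standard_normal((20, 6))
        )
        E = rng.standard_normal((6, 2))
        r1 = afab_test(data, E, "split_sample", r=0.5, seed=99)
        r2 = afab_test(data, E, "split_sample", r=0.5, seed=99)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value


class TestShrinkageSigmaTilde:
    def test_ridge_coefficient(self, rng):
        held = TwoSampleData(
            rng.standard_normal((10, 10)), rng.standard_normal((10, 10))
        )
        St = shrinkage_sigma_tilde(held)
        expected_ridge = 10 / (10.0 * 20)
        S = pooled_covariance(held)
        np.testing.assert_allclose(St - S, expected_ridge * np.eye(10), atol=1e-12)

    def test_zero_variance_gives_pure_ridge(self):
        held = TwoSampleData(np.ones((3, 4)), np.ones((2, 4)))
        St = shrinkage_sigma_tilde(held)
        np.testing.assert_allclose(St, (4 / 50.0) * np.eye(4), atol=1e-14)

    def test_eigenvalue_floor(self, rng):
        held = TwoSampleData(
            rng.standard_normal((6, 5)), rng.standard_normal((5, 5))
        )
        St = shrinkage_sigma_tilde(held)
        ridge = 5 / (10.0 * 11)
        assert np.linalg.eigvalsh(St).min() >= ridge - 1e-12


class TestRpTest:
    def test_identity_projection_is_hotelling(self, rng):
        p = 4
        data = TwoSampleData(
            rng.standard_normal((12, p)), rng.standard_normal((15, p))
        )
        res = rp_test(data, p, projection=np.eye(p))
        y, _ = difference_of_means(data)
        S = pooled_covariance(data)
        T = (12 * 15 / 27) * float(y @ np.linalg.solve(S, y))
        assert res.statistic == pytest.approx(T, rel=1e-10)
        assert res.p_value == pytest.approx(afab_pvalue(T, 12, 15, p))

    def test_seed_determinism(self, rng):
        data = TwoSampleData(
            rng.standard_normal((12, 8)), rng.standard_normal((15, 8))
        )
        assert rp_test(data, 3, seed=5).p_value == rp_test(data, 3, seed=5).p_value


class TestLevelUnderNull:
    @pytest.mark.parametrize("variant", ["naive", "split_sample", "rp"])
    def test_level(self, rng, variant):
        p, d, n1, n2, reps, alpha = 30, 3, 20, 20, 600, 0.05
        Sigma = make_covariance(p, 5, 50.0, 12)
        E, _ = make_embedding_basis(p, d, 13)
        hits = 0
        for _ in range(reps):
            data = simulate_two_sample(Sigma, np.zeros(p), n1, n2, rng)
            if variant == "rp":
                res = rp_test(data, d, seed=rng)
            else:
                res = afab_test(data, E, variant, r=0.66, seed=rng)
            hits += res.p_value <= alpha
        assert abs(hits / reps - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)
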