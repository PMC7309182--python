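"""GMM/EM refinement: oracles for every step, then loop-level properties."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import clone

from phytoskel.refine import (
    GMMParams,
    GMMSkeletonRefiner,
    e_step,
    gaussian_kernel,
    init_sigma2,
    local_pca_mu,
    m_step,
    membership,
    negative_log_likelihood,
    refine,
)
from phytoskel.tree import build_curve_tree, decompose_axes

from conftest import rmse_to_z_axis, straight_tube_case


class TestInitSigma2:
    def test_hand_computed_case(self):
        P = np.array([[0, 0, 0], [2, 0, 0.0]])
        S = np.array([[1, 0, 0.0]])
        assert init_sigma2(P, S) == pytest.approx(1 / 3, abs=1e-15)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, m = int(rng.integers(2, 200)), int(rng.integers(1, 20))
            P = rng.normal(0, 5, (n, 3))
            S = rng.normal(0, 5, (m, 3))
            brute = sum(
                np.sum((P[j] - S[i]) ** 2) for i in range(m) for j in range(n)
            ) / (3 * m * n)
            assert init_sigma2(P, S) == pytest.approx(brute, rel=1e-12)

    def test_scale_homogeneity(self):
        rng = np.random.default_rng(12)
        P, S = rng.normal(0, 2, (30, 3)), rng.normal(0, 2, (5, 3))
        assert init_sigma2(3 * P, 3 * S) == pytest.approx(9 * init_sigma2(P, S), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            init_sigma2(np.empty((0, 3)), np.zeros((1, 3)))


class TestLocalPCA:
    def test_coplanar_neighborhood_gives_zero(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(0, 1, (50, 2)), np.zeros(50)])
        mu = local_pca_mu(pts, k=20)
        assert np.all(mu < 1e-12)

    def test_isotropic_ball_approaches_one_third(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, (10_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * rng.uniform(0, 1, (10_000, 1)) ** (1 / 3)
        mu = local_pca_mu(pts, query=np.zeros((1, 3)), k=5000)
        assert mu[0] == pytest.approx(1 / 3, abs=0.02)

    def test_coincident_points_degenerate(self):
        pts = np.zeros((10, 3))
        mu = local_pca_mu(pts, k=5)
        assert np.all(mu == 0.0)

    def test_range(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (200, 3)) * [5, 1, 0.2]
        mu = local_pca_mu(pts, k=15)
        assert np.all(mu >= 0) and np.all(mu <= 1 / 3 + 1e-12)

    def test_radius_mode_agrees_on_dense_plane(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(0, 10, (500, 2)), np.zeros(500)])
        mu_r = local_pca_mu(pts, query=pts[:5], radius=1.0)
        assert np.all(mu_r < 1e-12)  # coplanar either way
        ball = rng.normal(0, 1, (2000, 3))
        mu_r = local_pca_mu(ball, query=np.zeros((1, 3)), radius=2.0)
        assert 0.2 < mu_r[0] <= 1 / 3


class TestMembership:
    def test_equal_descriptors(self):
        a = membership(np.array([0.1]), np.array([0.1]))
        assert a[0, 0] == 1.0

    def test_one_third_gap(self):
        a = membership(np.array([1 / 3]), np.array([0.0]), alpha_tune=1.0)
        assert a[0, 0] == pytest.approx(np.exp(-1 / 3), rel=1e-12)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        mu_s, mu_p = rng.uniform(0, 1 / 3, 5), rng.uniform(0, 1 / 3, 7)
        assert np.all(membership(mu_s, mu_p, 2.0) <= membership(mu_s, mu_p, 1.0) + 1e-15)


class TestEStep:
    def test_columns_normalize_even_at_extreme_distances(self):
        rng = np.random.default_rng(4)
        S = rng.normal(0, 1, (6, 3))
        P = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(0, 1, (5, 3)) + 1e4])
        alpha = rng.uniform(0.5, 1.0, (6, 25))
        p_old, outlier = e_step(P, S, alpha, sigma2=0.5, epsilon=0.1)
        np.testing.assert_allclose(p_old.sum(axis=0) + outlier, 1.0, atol=1e-9)
        assert np.all(p_old >= 0) and np.all(outlier >= 0)

    def test_single_component_no_outliers(self):
        P = np.random.default_rng(5).normal(0, 1, (10, 3))
        S = np.zeros((1, 3))
        p_old, outlier = e_step(P, S, np.ones((1, 10)), sigma2=1.0, epsilon=0.0)
        np.testing.assert_allclose(p_old, 1.0, atol=1e-12)
        np.testing.assert_allclose(outlier, 0.0)

    def test_symmetric_centroids_split_evenly(self):
        S = np.array([[-1, 0, 0], [1, 0, 0.0]])
        P = np.array([[0, 0.3, 0.0]])
        p_old, _ = e_step(P, S, np.ones((2, 1)), sigma2=0.7, epsilon=0.0)
        assert p_old[0, 0] == pytest.approx(p_old[1, 0], rel=1e-12)

    def test_far_point_is_outlier(self):
        """A point whose Gaussian exponent underflows goes to the uniform
        component; cross-checked with arbitrary-precision arithmetic."""
        from mpmath import mp, mpf, exp as mpexp

        S = np.array([[0, 0, 0], [1, 0, 0.0]])
        P = np.array([[60.0, 0, 0], [0.5, 0, 0.0]])
        sigma2, epsilon, n = 1.0, 0.1, 2
        p_old, outlier = e_step(P, S, np.ones((2, 2)), sigma2, epsilon)
        assert outlier[0] > 0.999
        # arbitrary-precision reference for the far column
        mp.dps = 60
        c = mpf(epsilon) * (2 * mp.pi * sigma2) ** mpf(1.5) / (n * (1 - mpf(epsilon)))
        terms = [mpexp(-mpf((60.0 - sx) ** 2) / (2 * sigma2)) for sx in (0.0, 1.0)]
        ref_outlier = c / (c + sum(terms))
        assert outlier[0] == pytest.approx(float(ref_outlier), rel=1e-9)

    def test_epsilon_one_rejected(self):
        with pytest.raises(ValueError):
            e_step(np.zeros((1, 3)), np.zeros((1, 3)), np.ones((1, 1)), 1.0, 1.0)


class TestNegativeLogLikelihood:
    def test_unit_density_gives_zero(self):
        # single coincident pair, sigma^2 = 1/(2 pi) makes the density 1
        P = S = np.zeros((1, 3))
        L = negative_log_likelihood(P, S, np.ones((1, 1)), 1 / (2 * np.pi), 0.0)
        assert L == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_distance(self):
        S = np.zeros((2, 3))
        alpha = np.ones((2, 3))
        P1 = np.random.default_rng(6).normal(0, 1, (3, 3))
        L1 = negative_log_likelihood(P1, S, alpha, 1.0, 0.0)
        L2 = negative_log_likelihood(P1 * 1.5, S, alpha, 1.0, 0.0)
        assert L2 > L1

    def test_pure_outlier_limit(self):
        n = 7
        P = np.random.default_rng(7).normal(0, 1, (n, 3))
        S = np.zeros((2, 3))
        L = negative_log_likelihood(P, S, np.ones((2, n)), 1.0, 1.0)
        assert L == pytest.approx(n * np.log(n), rel=1e-12)


class TestMStep:
    def _fixture(self):
        P = np.array([[0.0, 0.0, 0.0], [1.0, 0.2, 0.0], [0.1, 1.0, 0.5], [0.9, 0.9, 0.4]])
        S0 = np.array([[0.2, 0.1, 0.1], [0.8, 0.8, 0.3]])
        params = GMMParams(lambda_reg=5.0, beta_kernel=5.0)
        alpha = np.ones((2, 4))
        sigma2 = 0.3
        p_old, _ = e_step(P, S0, alpha, sigma2, 0.1)
        G = gaussian_kernel(S0, params.beta_kernel)
        return P, S0, p_old, G, sigma2, params

    def test_w_matches_numerical_minimizer(self):
        """The linear-system W agrees with a generic optimizer of the expected
        complete negative log-likelihood + smoothness penalty."""
        P, S0, p_old, G, sigma2, params = self._fixture()
        W, _, _ = m_step(P, S0, p_old, G, sigma2, params)

        def objective(w_flat):
            W_ = w_flat.reshape(2, 3)
            T = S0 + G @ W_
            data = sum(
                p_old[i, j] * np.sum((P[j] - T[i]) ** 2)
                for i in range(2) for j in range(4)
            ) / (2 * sigma2)
            penalty = 0.5 * params.lambda_reg * np.trace(W_.T @ G @ W_)
            return data + penalty

        res = minimize(objective, np.zeros(6), method="BFGS", tol=1e-14)
        np.testing.assert_allclose(W.ravel(), res.x, atol=1e-5)

    def test_sigma2_matches_double_sum(self):
        P, S0, p_old, G, sigma2, params = self._fixture()
        W, sigma2_new, _ = m_step(P, S0, p_old, G, sigma2, params)
        T = S0 + G @ W
        xi = p_old.sum()
        brute = sum(
            p_old[i, j] * np.sum((P[j] - T[i]) ** 2)
            for i in range(2) for j in range(4)
        ) / (3 * xi)
        assert sigma2_new == pytest.approx(brute, abs=1e-10)

    def test_stationary_when_centroids_at_posterior_means(self):
        rng = np.random.default_rng(8)
        P = rng.normal(0, 1, (30, 3))
        S0 = np.array([P[:15].mean(axis=0), P[15:].mean(axis=0)])
        # hard assignment posterior whose means are exactly S0
        p_old = np.zeros((2, 30))
        p_old[0, :15] = 1.0
        p_old[1, 15:] = 1.0
        G = gaussian_kernel(S0, 5.0)
        W, _, _ = m_step(P, S0, p_old, G, sigma2=0.5, params=GMMParams())
        assert np.max(np.abs(G @ W)) < 1e-8

    def test_epsilon_update_clipped(self):
        P, S0, p_old, G, sigma2, params = self._fixture()
        _, _, eps = m_step(P, S0, p_old, G, sigma2, params)
        assert 0.01 <= eps <= 0.99


class TestRefineLoop:
    def test_centered_skeleton_stays_centered(self):
        """A skeleton already on the axis of a noiseless-ish tube keeps its
        perpendicular centering: mean lateral displacement < 5% of the
        radius.  (The axial component is excluded: posterior means near the
        tube caps contract inward, a finite-tube end effect the smoothing
        kernel spreads along the axis; it does not affect centeredness.)"""
        cloud, _, ct = straight_tube_case(1.0, seed=9, zigzag=0.0)
        refined, trace = refine(cloud, ct, GMMParams())
        lateral = np.linalg.norm(
            (refined.all_points - ct.all_points)[:, :2], axis=1
        )
        assert float(lateral.mean()) < 0.05 * 1.0
        assert rmse_to_z_axis(refined.all_points) < 0.05 * 1.0

    def test_zigzag_rmse_strictly_decreases(self):
        cloud, pert, ct = straight_tube_case(1.0, seed=10)
        refined, trace = refine(cloud, ct, GMMParams())
        assert rmse_to_z_axis(refined.all_points) < rmse_to_z_axis(pert.nodes)

    def test_objective_non_increasing(self):
        cloud, _, ct = straight_tube_case(1.0, seed=13)
        _, trace = refine(cloud, ct, GMMParams())
        obj = np.array(trace.objective)
        assert np.all(np.diff(obj) <= 1e-6 * np.abs(obj[:-1]))

    def test_huge_lambda_freezes_points(self):
        cloud, _, ct = straight_tube_case(1.0, seed=14)
        refined, _ = refine(cloud, ct, GMMParams(lambda_reg=1e6, max_iter=30))
        disp = np.linalg.norm(refined.all_points - ct.all_points, axis=1)
        assert float(disp.max()) < 1e-3

    def test_rigid_motion_equivariance(self):
        cloud, _, ct = straight_tube_case(1.0, seed=15)
        params = GMMParams(max_iter=10)
        ref1, _ = refine(cloud, ct, params)
        ang = 0.7
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]]
        )
        b = np.array([3.0, -2.0, 5.0])
        ct_t = ct.with_points(ct.all_points @ R.T + b)
        ref2, _ = refine(cloud @ R.T + b, ct_t, params)
        np.testing.assert_allclose(
            ref2.all_points, ref1.all_points @ R.T + b, atol=1e-6
        )

    def test_empty_cloud_rejected(self):
        _, _, ct = straight_tube_case(1.0, seed=16)
        with pytest.raises(ValueError):
            refine(np.empty((0, 3)), ct, GMMParams())

    def test_estimator_front_end(self):
        cloud, _, ct = straight_tube_case(1.0, seed=17)
        est = GMMSkeletonRefiner(max_iter=15)
        assert clone(est).get_params()["max_iter"] == 15
        est.fit(cloud, curve_tree=ct)
        assert est.n_iter_ <= 15
        assert est.sigma2_ > 0 and 0 < est.epsilon_ < 1
        assert est.curve_tree_.all_points.shape == ct.all_points.shape
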