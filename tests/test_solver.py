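"""The joint optimizer: block-update kernels against closed-form and
certificate oracles, adaptive hyper-parameters, and end-to-end behavior."""

import warnings

import numpy as np
import pytest

from rpcatree.mst import TreeTopology
from rpcatree.postprocess import dedup_centers, hard_assign
from rpcatree.rpca import ObservedMatrix
from rpcatree.simulate import simulate_scsnv, simulate_shape2d
from rpcatree.solver import (
    Hyperparams,
    _coupling_matrix,
    _inv_sqrt_psd,
    augmented_objective,
    build_laplacian,
    default_K,
    fit,
    objective,
    select_hyperparams,
    update_A,
    update_B,
    update_C,
    update_E,
    update_R,
)


def _tree(K, edges):
    B = np.zeros((K, K), dtype=int)
    for i, j in edges:
        B[i, j] = B[j, i] = 1
    return TreeTopology(B)


class TestSelectHyperparams:
    def test_lam_square_full_mask(self):
        obs = ObservedMatrix(np.random.default_rng(0).normal(size=(100, 100)), None)
        assert select_hyperparams(obs).lam == pytest.approx(0.1)

    def test_theta_gamma_scaling(self):
        obs = ObservedMatrix(np.random.default_rng(0).normal(size=(100, 25)), None)
        h = select_hyperparams(obs)
        assert h.theta == pytest.approx(2.0)
        assert h.gamma == pytest.approx(2.0)

    @pytest.mark.parametrize("M,expected", [(300, 300), (1000, 200), (2000, 40)])
    def test_K_regimes(self, M, expected):
        assert default_K(M) == expected

    def test_constant_matrix_floors_sigma(self):
        obs = ObservedMatrix(np.ones((10, 4)), None)
        with pytest.warns(UserWarning):
            h = select_hyperparams(obs)
        assert h.sigma >= 1e-8

    def test_overrides_win(self):
        obs = ObservedMatrix(np.random.default_rng(0).normal(size=(20, 5)), None)
        h = select_hyperparams(obs, sigma=3.14, K=7)
        assert h.sigma == 3.14 and h.K == 7 and not h.adapt_sigma


class TestLaplacian:
    def test_path_graph(self):
        L = build_laplacian(_tree(3, [(0, 1), (1, 2)]))
        np.testing.assert_array_equal(L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_single_vertex(self):
        np.testing.assert_array_equal(build_laplacian(_tree(1, [])), [[0.0]])

    def test_star_psd_and_null_vector(self, rng):
        L = build_laplacian(_tree(4, [(0, 1), (0, 2), (0, 3)]))
        np.testing.assert_array_equal(np.diag(L), [3, 1, 1, 1])
        np.testing.assert_allclose(L @ np.ones(4), 0, atol=1e-12)
        assert np.linalg.eigvalsh(L).min() >= -1e-12


class TestUpdateC:
    def test_single_cluster_is_column_mean(self, rng):
        A = rng.normal(size=(6, 3))
        R = np.ones((6, 1))
        C = update_C(A, R, _tree(1, []), theta=1.0, gamma=1.0)
        np.testing.assert_allclose(C[0], A.mean(axis=0), atol=1e-10)

    def test_hard_assignment_theta_zero_gives_group_means(self, rng):
        A = rng.normal(size=(8, 4))
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        R = np.eye(2)[labels]
        C = update_C(A, R, _tree(2, [(0, 1)]), theta=1e-15, gamma=1.0)
        for k in (0, 1):
            np.testing.assert_allclose(C[k], A[labels == k].mean(axis=0), atol=1e-8)

    def test_matches_dense_linear_solve(self, rng):
        A = rng.normal(size=(4, 2))
        R = rng.dirichlet(np.ones(2), size=4)
        tree = _tree(2, [(0, 1)])
        theta, gamma = 0.7, 1.3
        C = update_C(A, R, tree, theta, gamma)
        H = (theta / gamma) * build_laplacian(tree) + np.diag(R.sum(axis=0))
        np.testing.assert_allclose(H @ C, R.T @ A, atol=1e-10)


class TestUpdateE:
    def test_observed_below_threshold_zeroed(self):
        X = np.array([[0.3]])
        A = np.zeros((1, 1))
        E = update_E(X, A, np.zeros((1, 1)), mu=1.0, lam=0.5, mask=np.ones((1, 1), bool))
        assert E[0, 0] == 0.0

    def test_all_missing_gives_exact_residual(self, rng):
        X = rng.normal(size=(3, 3))
        A = rng.normal(size=(3, 3))
        Lam = rng.normal(size=(3, 3))
        mu = 2.0
        E = update_E(X, A, Lam, mu, lam=0.4, mask=np.zeros((3, 3), bool))
        np.testing.assert_allclose(E, X - A + Lam / mu, atol=1e-12)

    def test_zero_lam_no_shrinkage(self, rng):
        X = rng.normal(size=(3, 3))
        A = rng.normal(size=(3, 3))
        Lam = rng.normal(size=(3, 3))
        E = update_E(X, A, Lam, mu=1.5, lam=0.0, mask=np.ones((3, 3), bool))
        np.testing.assert_allclose(E, X - A + Lam / 1.5, atol=1e-12)


class TestUpdateA:
    def test_lipschitz_constant_for_projector(self):
        # S with orthonormal columns: SS^T has eigenvalues {0, 1}, so
        # ||(mu+2g)I - 2g SS^T|| = mu+2g when M > K
        from rpcatree.solver import _lipschitz

        S = np.eye(6)[:, :2]
        assert _lipschitz(S, mu=1.0, gamma=1.0) == pytest.approx(3.0)

    def test_gamma_zero_limit_is_classical_rpca_step(self, rng):
        from rpcatree.rpca import svt

        X = rng.normal(size=(5, 4))
        A = rng.normal(size=(5, 4))
        E = rng.normal(size=(5, 4))
        Lam = rng.normal(size=(5, 4))
        mu = 2.0
        S = np.zeros((5, 2))
        gamma = 1e-14
        A_new, _ = update_A(A, X, E, S, Lam, mu, gamma)
        expected = svt(A - (-Lam + mu * (A - (X - E))) / mu, 1.0 / mu)
        np.testing.assert_allclose(A_new, expected, atol=1e-8)

    def test_fixed_point_satisfies_nuclear_norm_kkt(self, rng):
        """Iterating the prox step converges to the minimizer of the
        strongly convex subproblem; verified by the subdifferential
        certificate -grad f(A*) in d||A*||_*."""
        X = rng.normal(size=(6, 4))
        E = 0.1 * rng.normal(size=(6, 4))
        Lam = 0.05 * rng.normal(size=(6, 4))
        R = rng.dirichlet(np.ones(3), size=6)
        tree = _tree(3, [(0, 1), (1, 2)])
        theta = gamma = 0.8
        mu = 1.7
        H = _coupling_matrix(R, tree, theta, gamma)
        S = R @ _inv_sqrt_psd(H)
        A = X.copy()
        for _ in range(4000):
            A, svals = update_A(A, X, E, S, Lam, mu, gamma)
        G = -(-Lam + mu * (A - (X - E)) + 2 * gamma * (A - S @ (S.T @ A)))
        U, s, Vt = np.linalg.svd(A, full_matrices=True)
        r = int((s > 1e-8).sum())
        Ur, Vr = U[:, :r], Vt[:r].T
        # tangent part must equal U V^T, orthogonal part must have norm <= 1
        np.testing.assert_allclose(Ur.T @ G @ Vr, np.eye(r), atol=1e-5)
        W = U[:, r:].T @ G @ Vt[r:].T
        assert np.linalg.norm(W, 2) <= 1 + 1e-6

    def test_nonfinite_gradient_raises(self):
        X = np.full((3, 2), np.inf)
        with pytest.raises(FloatingPointError):
            update_A(np.zeros((3, 2)), X, np.zeros((3, 2)), np.zeros((3, 1)),
                     np.zeros((3, 2)), 1.0, 1.0)


class TestUpdateR:
    def test_equidistant_centers_uniform_row(self):
        A = np.zeros((1, 2))
        C = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        R = update_R(A, C, sigma=0.7)
        np.testing.assert_allclose(R[0], 0.25, atol=1e-12)

    def test_small_sigma_one_hot_at_nearest(self, rng):
        A = rng.normal(size=(10, 3))
        C = rng.normal(size=(4, 3))
        R = update_R(A, C, sigma=1e-10)
        d = ((A[:, None] - C[None]) ** 2).sum(-1)
        np.testing.assert_allclose(R, np.eye(4)[d.argmin(axis=1)], atol=1e-12)

    def test_two_center_closed_form(self):
        # distances 0 and 1 at sigma=1: softmax of (0, -1)
        A = np.zeros((1, 1))
        C = np.array([[0.0], [1.0]])
        R = update_R(A, C, sigma=1.0)
        assert R[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-10)
        assert R[0, 1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-10)

    def test_rows_sum_to_one_even_at_extreme_distances(self, rng):
        A = 1e4 * rng.normal(size=(20, 5))
        C = 1e4 * rng.normal(size=(6, 5))
        R = update_R(A, C, sigma=1e-6)
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-9)


class TestBlockUpdateMonotonicity:
    def test_each_block_never_increases_augmented_objective(self, rng):
        """At fixed (Lambda, mu) the B, R, E, A, C updates each decrease
        the augmented Lagrangian (the monotone-descent property the
        convergence analysis rests on), checked on random instances."""
        for trial in range(3):
            r = np.random.default_rng(trial)
            X = r.normal(size=(30, 10))
            mask = r.uniform(size=X.shape) > 0.1
            obs = ObservedMatrix(np.where(mask, X, 0.0), mask)
            hyper = select_hyperparams(obs, K=8)
            A = X.copy()
            C = r.normal(size=(8, 10))
            E = 0.1 * r.normal(size=X.shape)
            Lam = 0.1 * r.normal(size=X.shape)
            mu = 0.9
            B = update_B(C)
            R = update_R(A, C, hyper.sigma)

            def aug(A=A, E=E, C=C, R=R, B=B):
                return augmented_objective(X, mask, A, E, C, R, B, hyper, Lam, mu)

            vals = [aug()]
            B = update_B(C)
            vals.append(aug(B=B))
            R = update_R(A, C, hyper.sigma)
            vals.append(aug(R=R, B=B))
            E = update_E(X, A, Lam, mu, hyper.lam, mask)
            vals.append(aug(E=E, R=R, B=B))
            H = _coupling_matrix(R, B, hyper.theta, hyper.gamma)
            S = R @ _inv_sqrt_psd(H)
            A, _ = update_A(A, X, E, S, Lam, mu, hyper.gamma)
            vals.append(aug(A=A, E=E, R=R, B=B))
            C = update_C(A, R, B, hyper.theta, hyper.gamma)
            vals.append(aug(A=A, E=E, C=C, R=R, B=B))
            diffs = np.diff(vals)
            assert (diffs <= 1e-8).all(), diffs


class TestFit:
    def test_noiseless_blocks_recovered_exactly(self, rng):
        # 4 distinct rows repeated; in the theta->0 limit the centers
        # interpolate the data and the assignment is exact
        base = rng.normal(size=(4, 8))
        X = np.repeat(base, 15, axis=0)
        hyper = select_hyperparams(ObservedMatrix(X, None), K=8, theta=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = fit(X, hyper)
        labels = hard_assign(state.R)
        model = dedup_centers(state.C, labels)
        from rpcatree.metrics import ari

        assert ari(model.labels, np.repeat(np.arange(4), 15)) == 1.0
        assert np.linalg.norm(state.E) / np.linalg.norm(X) < 0.1

    def test_scsnv_recovery_small(self):
        """Clone structure recovered from a noisy discrete matrix; the
        full-size regime is exercised in the acceptance suite."""
        obs, truth = simulate_scsnv(200, 120, 3, [70, 60, 70], 0.20, 0.10, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = fit(obs, select_hyperparams(obs, seed=5, K=40))
        labels = hard_assign(state.R)
        model = dedup_centers(state.C, labels, kind="snv")
        from rpcatree.metrics import ari

        assert ari(model.labels, truth.labels) > 0.95

    def test_spiral_outliers_extracted_into_E(self):
        obs, truth = simulate_shape2d("spiral", 200, 3, 0.05, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = fit(obs)
        Enorm = np.linalg.norm(state.E, axis=1)
        med = np.median(Enorm)
        assert (Enorm[truth.outlier_index] > 5 * max(med, 1e-12)).all()

    def test_lower_bound_and_feasibility(self, rng):
        X = rng.normal(size=(30, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = fit(X, mode="exact")
        h = state.hyper
        bound = -h.gamma * h.sigma * 30 * np.log(h.K)
        assert all(v >= bound for v in state.objective_trace)
        assert state.residuals[-1] < 1e-6

    def test_exact_trace_monotone(self, rng):
        X = rng.normal(size=(30, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = fit(X, mode="exact")
        inc = np.diff(state.objective_trace)
        assert (inc[1:] <= 1e-8).all() if len(inc) > 1 else True

    def test_exact_and_inexact_objectives_agree(self, rng):
        X = rng.normal(size=(50, 20)) + np.outer(rng.normal(size=50), rng.normal(size=20))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(X, mode="inexact")
            b = fit(X, mode="exact")
        rel = abs(a.objective_trace[-1] - b.objective_trace[-1]) / abs(b.objective_trace[-1])
        assert rel < 0.01

    def test_invariants_of_returned_state(self, rng):
        X = rng.normal(size=(25, 6))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = fit(X)
        np.testing.assert_allclose(state.R.sum(axis=1), 1.0, atol=1e-9)
        assert state.B.n_vertices == state.C.shape[0]
        assert state.decomposition.A.shape == X.shape

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(20, 5))
        h = select_hyperparams(ObservedMatrix(X, None), seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(X, h)
            b = fit(X, h)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.R, b.R)

    def test_rejects_bad_arguments(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            fit(X, mode="sloppy")
        with pytest.raises(ValueError):
            fit(X, Hyperparams(lam=0.1, theta=1, gamma=1, sigma=1, K=99))
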