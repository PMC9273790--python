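"""Semi-supervised discriminant analysis: graphs, scatters, eigenproblem."""

import numpy as np
import pytest

from stmi import sda
from stmi.errors import DataError, ParameterError


def two_gaussians(rng, n=60, d=2, sep=4.0):
    X0 = rng.standard_normal((n // 2, d))
    X1 = rng.standard_normal((n // 2, d)) + sep / np.sqrt(d)
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


class TestAffinityGraph:
    def test_laplacian_rows_sum_to_zero(self, rng):
        X = rng.standard_normal((20, 3))
        g = sda.build_affinity_graph(X, p=4)
        assert np.allclose(g.L @ np.ones(20), 0.0)
        assert np.array_equal(g.S, g.S.T)
        assert np.all(np.diag(g.S) == 0)

    def test_laplacian_positive_semidefinite(self, rng):
        X = rng.standard_normal((15, 4))
        g = sda.build_affinity_graph(X, p=3)
        assert np.linalg.eigvalsh(g.L).min() > -1e-10

    def test_collinear_points_brute_force(self):
        """3 collinear points, p=1: brute-force all-pairs distances say the
        ends each pick the middle, so the middle ends with degree 2."""
        X = np.array([[0.0], [1.0], [3.0]])
        g = sda.build_affinity_graph(X, p=1)
        assert np.array_equal(g.S, [[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert g.D[1, 1] == 2

    def test_duplicated_points_are_connected(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        g = sda.build_affinity_graph(X, p=1)
        assert g.S[0, 1] == 1

    def test_p_too_large_raises(self, rng):
        with pytest.raises(ParameterError):
            sda.build_affinity_graph(rng.standard_normal((4, 2)), p=4)


class TestScatterMatrices:
    def test_singleton_classes_have_zero_within_scatter(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        sc = sda.scatter_matrices(X, np.array([0, 1]))
        assert np.allclose(sc.S_w, 0.0)
        assert np.allclose(sc.S_t, sc.S_b)

    def test_identical_points_give_zero_scatter(self):
        X = np.ones((6, 3))
        sc = sda.scatter_matrices(X, np.array([0, 0, 0, 1, 1, 1]))
        for M in (sc.S_b, sc.S_w, sc.S_t):
            assert np.allclose(M, 0.0)

    def test_six_point_example_against_term_by_term_oracle(self):
        """Hand summation of the scatter definitions on 6 fixed 2-D points."""
        X = np.array([[0, 0], [1, 0], [0, 1], [4, 4], [5, 4], [4, 5]], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        mu = X.mean(axis=0)
        S_b = np.zeros((2, 2))
        S_w = np.zeros((2, 2))
        for k in (0, 1):
            Xk = X[y == k]
            mk = Xk.mean(axis=0)
            S_b += len(Xk) * np.outer(mk - mu, mk - mu)
            for xi in Xk:
                S_w += np.outer(xi - mk, xi - mk)
        sc = sda.scatter_matrices(X, y)
        assert np.allclose(sc.S_b, S_b)
        assert np.allclose(sc.S_w, S_w)
        assert np.allclose(sc.S_t, S_b + S_w)

    def test_psd_and_additivity_on_random_data(self, rng):
        X, y = two_gaussians(rng, n=40, d=5)
        sc = sda.scatter_matrices(X, y)
        for M in (sc.S_b, sc.S_w, sc.S_t):
            assert np.linalg.eigvalsh(M).min() > -1e-8
        assert np.allclose(sc.S_t, sc.S_b + sc.S_w)

    def test_single_class_raises(self, rng):
        with pytest.raises(DataError):
            sda.scatter_matrices(rng.standard_normal((5, 2)), np.zeros(5, int))


class TestFitSDA:
    def test_lda_limit_matches_closed_form(self, rng):
        """beta=0 with no unlabeled data reproduces the classical two-class
        LDA direction S_w^-1 (mu_1 - mu_0) up to sign and scale."""
        X, y = two_gaussians(rng, n=80, d=2)
        sc = sda.scatter_matrices(X, y)
        lda_dir = np.linalg.solve(
            sc.S_w + 1e-10 * np.eye(2), sc.class_means[1] - sc.class_means[0]
        )
        model = sda.fit_sda(X, y, beta=0.0)
        a1 = model.A[:, 0]
        cos = abs(a1 @ lda_dir) / (np.linalg.norm(a1) * np.linalg.norm(lda_dir))
        assert cos > 0.999

    def test_returns_exactly_two_directions(self, rng):
        X, y = two_gaussians(rng, n=30, d=10)
        model = sda.fit_sda(X, y, beta=0.5, p=3)
        assert model.A.shape == (10, 2)
        assert model.eigenvalues[0] >= model.eigenvalues[1]

    def test_eigen_residual_certificate(self, rng):
        X, y = two_gaussians(rng, n=40, d=6)
        Xu = rng.standard_normal((20, 6))
        model = sda.fit_sda(X, y, Xu, beta=0.3, p=4)
        assert model.residual <= 1e-6

    def test_span_solver_equals_direct_solver(self, rng):
        """On d <= 50 with more samples than dimensions the span-restricted
        solver must agree with the dense solver up to column signs."""
        for d in (5, 20, 50):
            X, y = two_gaussians(rng, n=2 * d + 20, d=d)
            Xu = rng.standard_normal((10, d))
            m_dir = sda.fit_sda(X, y, Xu, beta=0.2, p=4, solver="direct")
            m_span = sda.fit_sda(X, y, Xu, beta=0.2, p=4, solver="span")
            z_dir = sda.transform(m_dir, X)
            z_span = sda.transform(m_span, X)
            for j in range(2):
                c = np.corrcoef(z_dir[:, j], z_span[:, j])[0, 1]
                assert abs(c) > 1 - 1e-6

    def test_rayleigh_quotient_nonincreasing_in_beta(self, rng):
        """The regularized objective at the fitted direction shrinks as the
        graph penalty grows."""
        X, y = two_gaussians(rng, n=40, d=3)
        quotients = []
        for beta in (0.0, 0.1, 1.0, 10.0, 100.0):
            model = sda.fit_sda(X, y, X.copy(), beta=beta, p=4)
            a = model.A[:, 0]
            sc = sda.scatter_matrices(X, y)
            L = sda.build_affinity_graph(np.vstack([X, X]), 4).L
            Xall = np.vstack([X, X])
            denom = a @ (sc.S_t + beta * Xall.T @ L @ Xall) @ a
            quotients.append((a @ sc.S_b @ a) / denom)
        assert all(a >= b - 1e-9 for a, b in zip(quotients, quotients[1:]))

    def test_high_dimensional_span_solver_beats_random_projection(self, rng):
        """1-NN accuracy in the 2-D SDA space >= accuracy in a random 2-D
        projection, averaged over 20 draws (d >> N regime)."""
        from sklearn.neighbors import KNeighborsClassifier

        d = 500
        wins = []
        for trial in range(20):
            r = np.random.default_rng(trial)
            X0 = r.standard_normal((15, d))
            X1 = r.standard_normal((15, d))
            X1[:, :10] += 2.0
            X = np.vstack([X0, X1])
            y = np.r_[np.zeros(15, int), np.ones(15, int)]
            Xt0 = r.standard_normal((10, d))
            Xt1 = r.standard_normal((10, d))
            Xt1[:, :10] += 2.0
            Xt = np.vstack([Xt0, Xt1])
            yt = np.r_[np.zeros(10, int), np.ones(10, int)]
            model = sda.fit_sda(X, y, beta=0.1, p=5, solver="span")
            z, zt = sda.transform(model, X), sda.transform(model, Xt)
            acc_sda = KNeighborsClassifier(1).fit(z, y).score(zt, yt)
            P = r.standard_normal((d, 2))
            acc_rand = KNeighborsClassifier(1).fit(X @ P, y).score(Xt @ P, yt)
            wins.append(acc_sda - acc_rand)
        assert np.mean(wins) >= 0.0

    def test_invalid_inputs(self, rng):
        X, y = two_gaussians(rng, n=20, d=3)
        with pytest.raises(ParameterError):
            sda.fit_sda(X, y, beta=-1.0)
        with pytest.raises(DataError):
            sda.fit_sda(X, np.zeros(20, int))


class TestTransform:
    def test_identity_block_projection(self, rng):
        X = rng.standard_normal((5, 4))
        A = np.eye(4)[:, :2]
        model = sda.SDAModel(
            A=A, eigenvalues=np.ones(2), beta=0.0, p=5, ridge=0.0,
            classes=np.array([0, 1]), residual=0.0,
        )
        assert np.allclose(sda.transform(model, X), X[:, :2])
        assert np.allclose(sda.transform(model, np.zeros(4)), 0.0)

    def test_dimension_mismatch_raises(self, rng):
        model = sda.fit_sda(*two_gaussians(rng, 20, 3))
        with pytest.raises(DataError):
            sda.transform(model, rng.standard_normal((4, 7)))


class TestPCA:
    def test_rank_one_data(self, rng):
        u = rng.standard_normal(8)
        X = np.outer(rng.standard_normal(30), u)
        pca = sda.fit_pca(X, 2)
        assert pca.explained_variance_ratio_[0] > 0.999

    def test_loadings_match_analytic_eigenvectors(self, rng):
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        Xc = rng.multivariate_normal([0, 0], cov, size=20000)
        pca = sda.fit_pca(Xc, 2)
        w, V = np.linalg.eigh(cov)
        top = V[:, np.argmax(w)]
        cos = abs(pca.components_[0] @ top)
        assert cos > 0.999

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ParameterError):
            sda.fit_pca(rng.standard_normal((5, 3)), 5)
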