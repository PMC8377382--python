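import math

import numpy as np
import pytest

from psfunc.pca import (
    CorrelationPCA,
    center_columns,
    component_selection,
    contributions,
    correlation_matrix,
    covariance_mode,
    eigendecompose,
    taxon_scores,
)

# ---------------------------------------------------------------------------
# independent naive oracles


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def power_iteration_eigh(X, n_iter=20_000, tol=1e-14):
    """Dominant-eigenpair power iteration with deflation on a PSD matrix."""
    X = X.copy().astype(float)
    J = X.shape[0]
    vals, vecs = [], []
    rng = np.random.default_rng(7)
    for _ in range(J):
        v = rng.standard_normal(J)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = X @ v
            norm = np.linalg.norm(w)
            if norm < 1e-13:
                lam = 0.0
                break
            w /= norm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                lam = float(v @ X @ v)
                break
            v = w
            lam = float(v @ X @ v)
        vals.append(max(lam, 0.0))
        vecs.append(v)
        X -= lam * np.outer(v, v)
    return np.array(vals), np.column_stack(vecs)


class TestCenterColumns:
    def test_constant_column_zeroed(self):
        Z = np.array([[2.0, 1.0], [2.0, 3.0]])
        np.testing.assert_allclose(center_columns(Z)[:, 0], 0.0)

    def test_small_example(self):
        np.testing.assert_allclose(
            center_columns(np.array([[1.0], [3.0]])), [[-1.0], [1.0]]
        )

    def test_random_columns_have_zero_mean(self, rng):
        Zc = center_columns(rng.random((5, 4)))
        np.testing.assert_allclose(Zc.mean(axis=0), 0.0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            center_columns(np.ones((1, 3)))


class TestCorrelationMatrix:
    def test_proportional_columns(self):
        Z = center_columns(np.array([[1.0, 2.0], [2.0, 4.0], [4.0, 8.0]]))
        X = correlation_matrix(Z)
        np.testing.assert_allclose(X, np.ones((2, 2)), atol=1e-12)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.array([[1.0], [2.0]]))

    def test_zero_variance_column_rejected(self):
        Z = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 4.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(center_columns(Z))

    def test_matches_textbook_formula(self, rng):
        Z = rng.random((6, 3))
        X = correlation_matrix(center_columns(Z))
        for a in range(3):
            for b in range(3):
                expected = naive_pearson(Z[:, a].tolist(), Z[:, b].tolist())
                assert X[a, b] == pytest.approx(expected, abs=1e-10)
        assert np.allclose(X, X.T)
        np.testing.assert_allclose(np.diag(X), 1.0)


class TestEigendecompose:
    def test_identity(self):
        vals, V = eigendecompose(np.eye(3))
        np.testing.assert_allclose(vals, 1.0)
        np.testing.assert_allclose(np.abs(V @ V.T), np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("r", [0.3, -0.7, 0.95])
    def test_two_by_two_closed_form(self, r):
        vals, V = eigendecompose(np.array([[1.0, r], [r, 1.0]]))
        np.testing.assert_allclose(sorted(vals, reverse=True), [1 + abs(r), 1 - abs(r)])
        np.testing.assert_allclose(np.abs(V), np.full((2, 2), 1 / math.sqrt(2)))

    def test_trace_preserved_and_signs_deterministic(self, rng):
        Z = rng.random((8, 5))
        X = correlation_matrix(center_columns(Z))
        vals, V = eigendecompose(X)
        assert vals.sum() == pytest.approx(5.0, abs=1e-8)
        assert np.all(vals[:-1] >= vals[1:])
        # largest-magnitude element of each eigenvector is positive
        for l in range(V.shape[1]):
            assert V[np.abs(V[:, l]).argmax(), l] > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            eigendecompose(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestTaxonScores:
    def test_identity_rotation(self, rng):
        Zc = center_columns(rng.random((4, 3)))
        np.testing.assert_array_equal(taxon_scores(Zc, np.eye(3)), Zc)

    def test_total_sum_of_squares_invariant(self, rng):
        Zc = center_columns(rng.random((6, 4)))
        _, V = eigendecompose(correlation_matrix(Zc))
        S = taxon_scores(Zc, V)
        assert (S**2).sum() == pytest.approx((Zc**2).sum(), rel=1e-9)

    def test_matches_naive_triple_loop(self, rng):
        Zc = center_columns(rng.random((4, 3)))
        V = rng.random((3, 3))
        S = taxon_scores(Zc, V)
        for i in range(4):
            for l in range(3):
                assert S[i, l] == pytest.approx(
                    sum(Zc[i, j] * V[j, l] for j in range(3))
                )


class TestComponentSelection:
    @pytest.mark.parametrize(
        "shares,expected",
        [((0.85, 0.10, 0.05), 1), ((0.5, 0.2, 0.2, 0.1), 3), ((0.1,) * 10, 8)],
    )
    def test_shortest_prefix(self, shares, expected):
        sel = component_selection(np.array(shares))
        assert sel.tolist() == list(range(expected))

    def test_cumulative_sum_oracle(self, rng):
        inertia = rng.random(9)
        sel = component_selection(inertia)
        shares = np.cumsum(inertia) / inertia.sum()
        n = len(sel)
        assert shares[n - 1] >= 0.80 - 1e-12
        if n > 1:
            assert shares[n - 2] < 0.80


class TestContributions:
    def test_single_nonzero_score(self):
        S = np.array([[2.0], [0.0]])
        C = contributions(S, np.array([4.0]))
        np.testing.assert_allclose(C, [[1.0], [0.0]])

    def test_columns_sum_to_one(self, rng):
        Zc = center_columns(rng.random((5, 3)))
        _, V = eigendecompose(correlation_matrix(Zc))
        S = taxon_scores(Zc, V)
        inertia = (S**2).sum(axis=0)
        C = contributions(S, inertia)
        np.testing.assert_allclose(C.sum(axis=0)[inertia > 1e-12], 1.0, atol=1e-9)

    def test_zero_inertia_gives_zero_column(self):
        C = contributions(np.zeros((3, 2)), np.array([0.0, 0.0]))
        np.testing.assert_array_equal(C, 0.0)

    def test_matches_direct_formula(self, rng):
        S = rng.random((5, 3))
        inertia = (S**2).sum(axis=0)
        C = contributions(S, inertia)
        for i in range(5):
            for l in range(3):
                assert C[i, l] == pytest.approx(S[i, l] ** 2 / inertia[l])


class TestCorrelationPCAEstimator:
    def test_invariants_on_random_data(self, rng):
        Z = rng.random((7, 5))
        pca = CorrelationPCA().fit(Z)
        V = pca.loadings_
        np.testing.assert_allclose(V.T @ V, np.eye(5), atol=1e-8)
        Zc = Z - Z.mean(axis=0)
        assert pca.inertia_.sum() == pytest.approx((Zc**2).sum(), rel=1e-6)
        assert pca.pct_inertia_.sum() == pytest.approx(100.0)
        # rank bound: nonzero components <= min(I-1, J)
        assert (pca.eigenvalues_ > 1e-8).sum() <= min(6, 5)

    def test_oracle_equivalence_small_random_matrices(self):
        """Eigenvalues and |loadings| match an independent power-iteration
        implementation to 1e-6 on random matrices up to 12 x 12."""
        rng = np.random.default_rng(3)
        for I, J in [(6, 4), (9, 7), (12, 12), (8, 12)]:
            Z = rng.random((I, J))
            pca = CorrelationPCA().fit(Z)
            X = correlation_matrix(center_columns(Z))
            vals, vecs = power_iteration_eigh(X)
            order = np.argsort(-vals, kind="stable")
            vals, vecs = vals[order], vecs[:, order]
            np.testing.assert_allclose(pca.eigenvalues_, vals, atol=1e-6)
            gaps_ok = np.concatenate(
                [[True], np.abs(np.diff(vals)) > 1e-4]
            ) & np.concatenate([np.abs(np.diff(vals)) > 1e-4, [True]])
            for l in np.flatnonzero(gaps_ok & (vals > 1e-8)):
                np.testing.assert_allclose(
                    np.abs(pca.loadings_[:, l]), np.abs(vecs[:, l]), atol=1e-6
                )

    def test_permutation_equivariance(self, rng):
        Z = rng.random((6, 5))
        pca = CorrelationPCA().fit(Z)
        row_perm = rng.permutation(6)
        pca_r = CorrelationPCA().fit(Z[row_perm])
        np.testing.assert_allclose(pca_r.scores_, pca.scores_[row_perm], atol=1e-9)
        col_perm = rng.permutation(5)
        pca_c = CorrelationPCA().fit(Z[:, col_perm])
        np.testing.assert_allclose(
            np.abs(pca_c.loadings_), np.abs(pca.loadings_[col_perm]), atol=1e-9
        )

    def test_degenerate_columns_dropped_with_warning(self, rng, caplog):
        Z = rng.random((6, 4))
        Z[:, 2] = 0.7
        with caplog.at_level("WARNING"):
            pca = CorrelationPCA().fit(Z)
        assert pca.dropped_columns_.tolist() == [2]
        assert pca.loadings_.shape == (3, 3)

    def test_all_constant_fails(self):
        with pytest.raises(ValueError, match="constant"):
            CorrelationPCA().fit(np.ones((4, 3)))

    def test_transform_matches_scores(self, rng):
        Z = rng.random((6, 4))
        pca = CorrelationPCA().fit(Z)
        np.testing.assert_allclose(pca.transform(Z), pca.scores_, atol=1e-12)

    def test_sklearn_params_round_trip(self):
        pca = CorrelationPCA(mode="covariance", threshold=0.9)
        params = pca.get_params()
        assert params["mode"] == "covariance"
        clone = CorrelationPCA().set_params(**params)
        assert clone.threshold == 0.9

    def test_standardized_scaling_recovers_eigenvalue_inertia(self, rng):
        """With standardized scores the per-component inertia is proportional
        to the eigenvalues of the correlation matrix."""
        Z = rng.random((9, 4))
        pca = CorrelationPCA(score_scaling="standardized").fit(Z)
        ratio = pca.inertia_ / pca.eigenvalues_
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)


class TestCovarianceMode:
    def test_orthogonal_columns_variance_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(400)
        b = rng.standard_normal(400)
        a = (a - a.mean()) / a.std(ddof=1) * 2.0  # variance 4
        b = (b - b.mean()) / b.std(ddof=1)  # variance 1
        b = b - (b @ a) / (a @ a) * a  # orthogonalise
        b = b / b.std(ddof=1)
        Z = np.column_stack([a, b])
        pca = covariance_mode(Z)
        assert pca.eigenvalues_[0] / pca.eigenvalues_[1] == pytest.approx(4.0, rel=1e-6)

    def test_agrees_with_correlation_when_variances_equal(self, rng):
        Z = rng.random((8, 3))
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)  # all variances 1
        cov = covariance_mode(Z)
        cor = CorrelationPCA().fit(Z)
        np.testing.assert_allclose(cov.eigenvalues_, cor.eigenvalues_, atol=1e-9)
        np.testing.assert_allclose(
            np.abs(cov.loadings_), np.abs(cor.loadings_), atol=1e-8
        )

    def test_zero_variance_columns_permitted(self):
        Z = np.array([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]])
        pca = covariance_mode(Z)
        assert pca.loadings_.shape == (2, 2)
        assert pca.eigenvalues_[1] == pytest.approx(0.0, abs=1e-12)
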