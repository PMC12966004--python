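import numpy as np
import pandas as pd
import pytest
import sympy

import heattol as ht
from heattol.errors import DegenerateComponentError, DegenerateIndexError, DomainError
from conftest import random_coefficient_matrix


def cm_from(array, columns=None) -> ht.CoefficientMatrix:
    arr = np.asarray(array, dtype=float)
    return ht.CoefficientMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=columns or [f"ix{j}" for j in range(arr.shape[1])],
        )
    )


class TestStandardize:
    def test_symmetric_column_z_scores(self):
        z = ht.standardize_matrix(cm_from([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_rejected_by_name(self):
        with pytest.raises(DegenerateIndexError, match="ix1"):
            ht.standardize_matrix(cm_from([[1, 0.8], [2, 0.8], [3, 0.8]]))

    def test_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        z = ht.standardize_matrix(random_coefficient_matrix(rng, 8, 5))
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.var(ddof=1), 1.0, atol=1e-12)


class TestPrincipalComponents:
    def test_two_index_closed_form_one_plus_minus_r(self):
        """For a 2x2 correlation matrix the eigenvalues are 1 +/- r."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 2.0, 12)
        y = 0.6 * x + rng.uniform(0, 1.0, 12)
        cm = cm_from(np.column_stack([x, y]))
        r = np.corrcoef(x, y)[0, 1]
        pca = ht.principal_components(ht.standardize_matrix(cm))
        np.testing.assert_allclose(pca.eigenvalues, [1 + r, 1 - r], atol=1e-10)

    def test_uncorrelated_columns_give_unit_eigenvalues(self):
        # exactly orthogonal centered contrasts -> identity correlation matrix
        cm = cm_from(np.column_stack([[2, 4, 6, 8], [3, 1, 1, 3]]))
        pca = ht.principal_components(ht.standardize_matrix(cm))
        np.testing.assert_allclose(pca.eigenvalues, [1.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("n,p", [(6, 3), (7, 4)])
    def test_eigenvalues_match_characteristic_polynomial_oracle(self, n, p):
        """Independent oracle: roots of det(C - lambda I) via sympy."""
        rng = np.random.default_rng(n * 100 + p)
        cm = random_coefficient_matrix(rng, n, p)
        z = ht.standardize_matrix(cm)
        pca = ht.principal_components(z)
        corr = z.to_numpy().T @ z.to_numpy() / (n - 1)
        lam = sympy.symbols("lam")
        poly = sympy.Matrix(corr).charpoly(lam)
        coeffs = np.array([float(c) for c in poly.all_coeffs()])
        roots = sorted(np.roots(coeffs).real, reverse=True)
        np.testing.assert_allclose(pca.eigenvalues, roots, atol=1e-8)
        # the returned loadings are true orthonormal eigenvectors
        V = pca.loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(p), atol=1e-8)
        np.testing.assert_allclose(corr @ V, V * pca.eigenvalues, atol=1e-8)

    def test_agrees_with_sklearn_pca(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(42)
        cm = random_coefficient_matrix(rng, 10, 5)
        z = ht.standardize_matrix(cm)
        pca = ht.principal_components(z, ht.AnalysisConfig(n_components_override=5))
        ref = sklearn.PCA(n_components=5).fit(z.to_numpy())
        np.testing.assert_allclose(pca.eigenvalues, ref.explained_variance_, atol=1e-10)
        for k in range(5):  # same axes up to sign
            dot = abs(ref.components_[k] @ pca.loadings.to_numpy()[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_eigenvalues_sum_to_index_count(self):
        rng = np.random.default_rng(3)
        cm = random_coefficient_matrix(rng, 9, 6)
        pca = ht.principal_components(ht.standardize_matrix(cm))
        assert pca.eigenvalues.sum() == pytest.approx(6.0, abs=1e-10)
        assert pca.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_retention_by_threshold_and_override(self):
        rng = np.random.default_rng(4)
        cm = random_coefficient_matrix(rng, 10, 5)
        z = ht.standardize_matrix(cm)
        pca = ht.principal_components(z, ht.AnalysisConfig(variance_threshold=0.80))
        cum = np.cumsum(pca.proportions)
        m = pca.n_retained
        assert cum[m - 1] >= 0.80 and (m == 1 or cum[m - 2] < 0.80)
        forced = ht.principal_components(z, ht.AnalysisConfig(n_components_override=4))
        assert forced.n_retained == 4

    def test_override_beyond_rank_is_error(self):
        # rank-1 matrix: every column a multiple of the same latent vector
        theta = np.array([0.1, 0.4, 0.7, 0.9])
        cm = cm_from(np.column_stack([0.3 + 0.7 * theta, 1 + theta, 2 - theta]))
        z = ht.standardize_matrix(cm)
        with pytest.raises(DomainError, match="rank"):
            ht.principal_components(z, ht.AnalysisConfig(n_components_override=3))

    def test_anchor_orientation_makes_anchor_loading_non_negative(self):
        rng = np.random.default_rng(5)
        cm = random_coefficient_matrix(rng, 10, 4)
        cm = ht.CoefficientMatrix(cm.h.rename(columns={"ix0": "Chl a"}))
        pca = ht.principal_components(
            ht.standardize_matrix(cm), ht.AnalysisConfig(anchor_index="Chl a")
        )
        assert (pca.loadings.loc["Chl a"] >= -1e-10).all()


class TestMembership:
    def test_linear_min_max(self):
        scores = pd.DataFrame({"PC1": [2.0, 5.0, 8.0]}, index=list("abc"))
        u = ht.membership_values(scores)
        np.testing.assert_allclose(u["PC1"], [0.0, 0.5, 1.0])

    def test_two_point_case(self):
        u = ht.membership_values(pd.DataFrame({"PC1": [-1.0, 1.0]}, index=list("ab")))
        np.testing.assert_allclose(u["PC1"], [0.0, 1.0])

    def test_invariant_to_increasing_affine_transform(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(8, 3)), columns=["PC1", "PC2", "PC3"])
        u1 = ht.membership_values(scores)
        u2 = ht.membership_values(scores * 3.7 + 11.0)
        pd.testing.assert_frame_equal(u1, u2, atol=1e-12)

    def test_degenerate_component_rejected(self):
        scores = pd.DataFrame({"PC1": [1.0, 2.0], "PC2": [4.0, 4.0]}, index=list("ab"))
        with pytest.raises(DegenerateComponentError, match="PC2"):
            ht.membership_values(scores)


class TestWeightsAndH:
    def test_published_style_proportions_normalise_as_expected(self):
        """Retained proportions (0.54617, 0.17854, 0.11072) -> weights by
        hand division with their sum 0.83543."""
        props = np.array([0.54617, 0.17854, 0.11072, 0.16457 / 2, 0.16457 / 2])
        pca = ht.PCAResult(
            eigenvalues=props * 5,
            proportions=props,
            loadings=pd.DataFrame(np.eye(5)),
            scores=pd.DataFrame(np.zeros((3, 3)), columns=["PC1", "PC2", "PC3"]),
            n_retained=3,
            cumulative_retained=float(props[:3].sum()),
        )
        w = ht.component_weights(pca)
        np.testing.assert_allclose(
            w.to_numpy(),
            [0.54617 / 0.83543, 0.17854 / 0.83543, 0.11072 / 0.83543],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            w.to_numpy(), [0.65376, 0.21371, 0.13253], atol=5e-6
        )
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "u_row,w,expected",
        [
            ([1.0, 1.0, 1.0], [0.5, 0.3, 0.2], 1.0),
            ([0.0, 0.0, 0.0], [0.5, 0.3, 0.2], 0.0),
            ([1.0, 0.0], [0.75, 0.25], 0.75),
        ],
    )
    def test_h_is_weighted_membership_sum(self, u_row, w, expected):
        cols = [f"PC{i + 1}" for i in range(len(w))]
        u = pd.DataFrame([u_row], index=["g"], columns=cols)
        scores = ht.tolerance_values(u, pd.Series(w, index=cols))
        assert scores.h["g"] == pytest.approx(expected, abs=1e-12)


class TestEndToEnd:
    def test_affine_invariance_of_h(self):
        """a*x + b (a > 0) on any single coefficient column changes no H."""
        rng = np.random.default_rng(7)
        cm = random_coefficient_matrix(rng, 10, 5)
        _, base = ht.score_matrix(cm)
        for j, (a, b) in enumerate([(2.5, 0.3), (0.2, 1.0), (7.0, 0.0)]):
            h2 = cm.h.copy()
            col = h2.columns[j]
            h2[col] = a * h2[col] + b
            _, shifted = ht.score_matrix(ht.CoefficientMatrix(h2))
            np.testing.assert_allclose(base.h, shifted.h, atol=1e-10)

    def test_rank_one_limit_recovers_latent_order(self):
        """If all columns are affine in one latent vector, PC1 explains
        everything and H is strictly monotone in the latent vector."""
        theta = np.array([0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95])
        cols = {
            "Chl a": 0.3 + 0.7 * theta,
            "CAT": 1.0 + 1.5 * theta,
            "HL": 2.2 - 1.0 * theta,
        }
        cm = ht.CoefficientMatrix(
            pd.DataFrame(cols, index=[f"g{i}" for i in range(len(theta))])
        )
        pca, scores = ht.score_matrix(cm)
        assert pca.proportions[0] == pytest.approx(1.0, abs=1e-12)
        assert pca.n_retained == 1
        assert (np.diff(scores.h.to_numpy()) > 0).all()

    def test_h_invariant_to_score_scaling_convention(self):
        """Eigenvalue-scaled scores give the same H as unit-norm scores:
        the membership normalisation absorbs the per-component scale."""
        rng = np.random.default_rng(8)
        cm = random_coefficient_matrix(rng, 10, 4)
        pca, base = ht.score_matrix(cm)
        scaled = pca.scores * np.sqrt(pca.eigenvalues[: pca.n_retained])
        u = ht.membership_values(scaled)
        alt = ht.tolerance_values(u, ht.component_weights(pca))
        np.testing.assert_allclose(base.h, alt.h, atol=1e-12)
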