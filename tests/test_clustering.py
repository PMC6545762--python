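"""Random-forest proximities, classical MDS, silhouette separation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.tree import DecisionTreeClassifier

import ensemblefs as efs
from ensemblefs.clustering import ProximityMatrix, label_separation, mds_embed, proximity_matrix
from ensemblefs.learners import Forest, fit_random_forest


class _LeafOracle:
    """Minimal forest stand-in: fixed leaf assignments per tree."""

    def __init__(self, leaves):
        self.leaves = np.asarray(leaves)

    def apply(self, X):
        return self.leaves


class TestProximity:
    def test_single_stump_pencil_and_paper(self):
        # one tree splitting at x > 0; subjects at -1, -1, +1:
        # the two negatives share a leaf, the positive sits alone
        X = np.array([[-1.0], [-1.0], [1.0]])
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(
            np.array([[-1.0], [1.0]]), [0, 1]
        )
        forest = Forest(estimators=[tree], inbag_indices=[np.array([0, 1])], n_samples=2)
        prox = proximity_matrix(forest, X)
        np.testing.assert_allclose(
            prox.values, [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        )

    def test_duplicated_subjects_have_unit_proximity(self):
        t = efs.generate_cohort(efs.GeneratorSpec(n_subjects=60, seed=0))
        t = efs.derive_outcomes(efs.preprocess(t))
        X = t[list(efs.CANDIDATES)].to_numpy()
        X[1] = X[0]  # duplicate row
        _, forest = fit_random_forest(X, t["obw"].to_numpy(), n_trees=60, seed=0)
        prox = proximity_matrix(forest, X)
        assert prox.values[0, 1] == 1.0

    def test_definitional_invariants(self):
        t = efs.derive_outcomes(efs.preprocess(efs.generate_cohort(efs.GeneratorSpec(n_subjects=80, seed=2))))
        X = t[list(efs.CANDIDATES)].to_numpy()
        _, forest = fit_random_forest(X, t["obw"].to_numpy(), n_trees=80, seed=2)
        prox = proximity_matrix(forest, X)
        v = prox.values
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 1.0)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            ProximityMatrix(values=np.array([[1.0, 2.0], [2.0, 1.0]]), n_trees_used=1)


class TestMds:
    def test_two_point_closed_form(self):
        # prox 0.19 -> d^2 = 0.81, d = 0.9: points at +/- 0.45
        prox = ProximityMatrix(values=np.array([[1.0, 0.19], [0.19, 1.0]]), n_trees_used=100)
        emb = mds_embed(prox, dims=1)
        d = abs(emb.coordinates[0, 0] - emb.coordinates[1, 0])
        assert d == pytest.approx(0.9, abs=1e-12)
        np.testing.assert_allclose(np.sort(emb.coordinates[:, 0]), [-0.45, 0.45], atol=1e-12)

    def test_exact_euclidean_configuration_recovered(self):
        # build proximities from known 2-D points, embed, compare distances
        rng = np.random.default_rng(4)
        pts = rng.uniform(-0.4, 0.4, (15, 2))
        d2 = pdist(pts) ** 2
        from scipy.spatial.distance import squareform

        prox = ProximityMatrix(values=1.0 - squareform(d2), n_trees_used=1)
        emb = mds_embed(prox, dims=2)
        np.testing.assert_allclose(
            np.sort(pdist(emb.coordinates)), np.sort(pdist(pts)), atol=1e-6
        )

    def test_block_proximity_two_locations(self):
        v = np.ones((6, 6))
        v[:3, 3:] = 0.0
        v[3:, :3] = 0.0
        with pytest.warns(UserWarning, match="rank"):  # 1-D geometry, 2 dims
            emb = mds_embed(ProximityMatrix(values=v, n_trees_used=1), dims=2)
        a, b = emb.coordinates[:3], emb.coordinates[3:]
        np.testing.assert_allclose(a - a[0], 0.0, atol=1e-9)
        np.testing.assert_allclose(b - b[0], 0.0, atol=1e-9)
        assert np.linalg.norm(a[0] - b[0]) > 0.5

    def test_embedding_centered_and_ordered(self):
        t = efs.derive_outcomes(efs.preprocess(efs.generate_cohort(efs.GeneratorSpec(n_subjects=90, seed=5))))
        X = t[list(efs.CANDIDATES)].to_numpy()
        _, forest = fit_random_forest(X, t["obw"].to_numpy(), n_trees=60, seed=5)
        emb = mds_embed(proximity_matrix(forest, X))
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-8)
        assert (np.diff(emb.eigenvalues) <= 1e-9).all()

    def test_excess_dims_padded_with_warning(self):
        prox = ProximityMatrix(values=np.array([[1.0, 0.5], [0.5, 1.0]]), n_trees_used=1)
        with pytest.warns(UserWarning, match="rank"):
            emb = mds_embed(prox, dims=2)
        np.testing.assert_allclose(emb.coordinates[:, 1], 0.0)

    def test_distances_monotone_in_dissimilarity(self):
        t = efs.derive_outcomes(efs.preprocess(efs.generate_cohort(efs.GeneratorSpec(n_subjects=100, seed=6))))
        X = t[list(efs.CANDIDATES)].to_numpy()
        _, forest = fit_random_forest(X, t["obw"].to_numpy(), n_trees=150, seed=6)
        prox = proximity_matrix(forest, X)
        emb = mds_embed(prox, dims=40)  # near-full rank: ordering preserved
        iu = np.triu_indices(len(X), k=1)
        rho = spearmanr(np.sqrt(1 - prox.values[iu]), pdist(emb.coordinates)).statistic
        assert rho > 0.9


class TestLabelSeparation:
    def test_planted_clusters_high_silhouette(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(3, 0.2, (30, 2))])
        emb = type("E", (), {"coordinates": pts})()
        labels = np.repeat([0, 1], 30)
        assert label_separation(emb, labels) > 0.5

    def test_random_labels_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            emb = type("E", (), {"coordinates": rng.standard_normal((60, 2))})()
            vals.append(label_separation(emb, rng.integers(0, 2, 60)))
        assert abs(np.mean(vals)) < 0.1

    def test_degenerate_identical_points(self):
        emb = type("E", (), {"coordinates": np.zeros((10, 2))})()
        assert label_separation(emb, np.repeat([0, 1], 5)) == 0.0

    def test_single_label_rejected(self):
        emb = type("E", (), {"coordinates": np.zeros((4, 2))})()
        with pytest.raises(ValueError, match="label"):
            label_separation(emb, np.zeros(4))
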