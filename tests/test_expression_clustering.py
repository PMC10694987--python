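"""Signature clustering, permutation validation and the 2x2 chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from gbpath import expression_clustering as ec


class TestSubsetSignature:
    def test_subsets_and_warns_on_absent(self):
        expr = pd.DataFrame(
            np.ones((3, 4)), index=["a", "b", "c"], columns=list("wxyz")
        )
        with pytest.warns(UserWarning, match="absent"):
            sub = ec.subset_signature(expr, ["a", "c", "missing"])
        assert list(sub.index) == ["a", "c"]

    def test_too_few_present_rejected(self):
        expr = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        with pytest.raises(ValueError, match="signature genes present"):
            ec.subset_signature(expr, ["a", "zzz"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ec.subset_signature(pd.DataFrame(), [])


class TestEmbedSamples:
    def test_deterministic_and_shaped(self, clustered_expression):
        data, _ = clustered_expression
        a = ec.embed_samples(data, perplexity=10, seed=4)
        b = ec.embed_samples(data, perplexity=10, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.columns) == ["tsne_1", "tsne_2"]
        assert list(a.index) == list(data.columns)

    def test_perplexity_constraint_message(self, clustered_expression):
        data, _ = clustered_expression
        with pytest.raises(ValueError, match="largest valid perplexity"):
            ec.embed_samples(data, perplexity=25)

    def test_clusters_separate_in_embedding(self, clustered_expression):
        data, labels = clustered_expression
        emb = ec.embed_samples(data, perplexity=10, seed=4).to_numpy()
        # Cluster centroids in t-SNE space are far apart relative to spread.
        within = []
        centroids = {}
        for c in sorted(labels.unique()):
            pts = emb[(labels == c).to_numpy()]
            centroids[c] = pts.mean(axis=0)
            within.append(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())
        cents = np.array(list(centroids.values()))
        d01 = np.linalg.norm(cents[0] - cents[1])
        assert d01 > 2 * max(within)


class TestKmeansSilhouette:
    def test_recovers_true_k(self, clustered_expression):
        data, labels = clustered_expression
        res = ec.kmeans_silhouette(data, k_range=range(2, 8), seed=0)
        assert res.k == 3
        assert adjusted_rand_score(labels, res.labels) > 0.95
        assert set(res.silhouette_by_k.index) == set(range(2, 8))

    def test_labels_are_one_based(self, clustered_expression):
        data, _ = clustered_expression
        res = ec.kmeans_silhouette(data, k_range=range(2, 5), seed=0)
        assert res.labels.min() == 1

    def test_invalid_k_range(self, clustered_expression):
        data, _ = clustered_expression
        with pytest.raises(ValueError, match="k_range"):
            ec.kmeans_silhouette(data, k_range=[1, 2])


class TestScrambleGenes:
    def test_preserves_marginals_destroys_rows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        Xp = ec.scramble_genes(X, np.random.default_rng(1))
        assert np.allclose(np.sort(Xp, axis=0), np.sort(X, axis=0))
        assert not np.array_equal(Xp, X)


class TestPermutationTest:
    def test_real_clusters_give_small_p(self, clustered_expression):
        data, _ = clustered_expression
        assignment = ec.kmeans_silhouette(data, k_range=range(2, 5), seed=0)
        res = ec.permutation_cluster_test(data, assignment, n_perm=99, seed=0)
        assert res.empirical_p == pytest.approx(1 / 100)
        assert res.observed_between > res.observed_within
        assert len(res.null_separations) == 99

    def test_add_one_rule_p_never_zero(self, clustered_expression):
        data, _ = clustered_expression
        assignment = ec.kmeans_silhouette(data, k_range=range(2, 5), seed=0)
        res = ec.permutation_cluster_test(data, assignment, n_perm=19, seed=1)
        assert res.empirical_p >= 1 / 20

    def test_deterministic(self, clustered_expression):
        data, _ = clustered_expression
        assignment = ec.kmeans_silhouette(data, k_range=range(2, 5), seed=0)
        a = ec.permutation_cluster_test(data, assignment, n_perm=29, seed=5)
        b = ec.permutation_cluster_test(data, assignment, n_perm=29, seed=5)
        assert np.array_equal(a.null_separations, b.null_separations)

    def test_singleton_cluster_rejected(self, clustered_expression):
        data, _ = clustered_expression
        assignment = ec.kmeans_silhouette(data, k_range=range(2, 5), seed=0)
        assignment.labels.iloc[:] = 1
        assignment.labels.iloc[0] = 2
        with pytest.raises(ValueError, match="singleton"):
            ec.permutation_cluster_test(data, assignment, n_perm=9)


class TestChi2Yates:
    def test_matches_scipy_continuity_correction(self):
        # scipy adjusts each observed count 0.5 toward expected without
        # clamping, so the implementations only agree when |O - E| >= 0.5;
        # near-independent tables are covered by the clamping test below.
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 50:
            table = rng.integers(1, 60, (2, 2)).astype(float)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if np.abs(table - expected).min() < 0.5:
                continue
            mine = ec.chi2_2x2_yates(table)
            chi2, p, df, _ = stats.chi2_contingency(table, correction=True)
            assert mine["chi2"] == pytest.approx(chi2, abs=1e-10)
            assert mine["p"] == pytest.approx(p, abs=1e-12)
            assert mine["df"] == df == 1
            checked += 1

    def test_correction_clamps_at_zero(self):
        # |O - E| < 0.5 in every cell: the corrected statistic is exactly 0.
        res = ec.chi2_2x2_yates([[10, 10], [10, 10]])
        assert res["chi2"] == 0.0
        assert res["p"] == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ec.chi2_2x2_yates([[1.5, 2], [3, 4]])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ec.chi2_2x2_yates([[0, 0], [3, 4]])

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            ec.chi2_2x2_yates([[1, 2, 3], [4, 5, 6]])
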