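"""Model-selection rules and the four auto-tuned clustering engines."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.datasets import make_blobs

import gcscreen as g
from gcscreen.clustering import default_k_range, wcss_table


class TestChooseKElbow:
    def test_max_second_difference(self):
        assert g.choose_k_elbow({1: 100, 2: 40, 3: 30, 4: 28, 5: 27}) == 2

    def test_later_elbow(self):
        assert g.choose_k_elbow({1: 100, 2: 90, 3: 30, 4: 28}) == 3

    def test_linear_decay_ties_to_smallest_k(self):
        assert g.choose_k_elbow({k: 100 - 10 * k for k in range(1, 6)}) == 2

    def test_short_range_errors(self):
        with pytest.raises(ValueError, match=">=3"):
            g.choose_k_elbow({1: 10, 2: 5})


class TestChooseKSilhouette:
    @pytest.mark.parametrize("centers", [2, 3])
    def test_recovers_blob_count(self, centers):
        X, _ = make_blobs(n_samples=30, centers=centers, cluster_std=0.3,
                          random_state=7)
        k, s = g.choose_k_silhouette(X, seed=7)
        assert k == centers
        assert s > 0.5

    def test_single_blob_reports_weak_silhouette(self):
        # a structureless blob still yields a k >= 2, but its silhouette is
        # far below that of genuinely separated clusters (warning material)
        X1, _ = make_blobs(n_samples=20, centers=1, cluster_std=1.0, random_state=7)
        X3, _ = make_blobs(n_samples=20, centers=3, cluster_std=0.3, random_state=7)
        _, s1 = g.choose_k_silhouette(X1, seed=7)
        _, s3 = g.choose_k_silhouette(X3, seed=7)
        assert s1 < 0.6 < s3


class TestKMeansAuto:
    def test_k_is_max_of_elbow_and_silhouette(self, standardized):
        r = g.cluster_kmeans_auto(standardized, seed=17)
        assert r.k == max(r.diagnostics["k_elbow"], r.diagnostics["k_silhouette"])

    def test_agreement_case(self):
        X, _ = make_blobs(n_samples=40, centers=4, cluster_std=0.2, random_state=3)
        r = g.cluster_kmeans_auto(X, seed=3)
        assert r.diagnostics["k_elbow"] <= r.k
        assert r.k == 4

    def test_recovers_seven_archetypes(self, standardized, species):
        r = g.cluster_kmeans_auto(standardized, seed=17)
        assert g.adjusted_rand_index(r.labels, species.to_numpy()) == pytest.approx(1.0)


class TestGMMAuto:
    def test_two_separated_blobs(self):
        X, y = make_blobs(n_samples=60, centers=2, cluster_std=0.3, random_state=11)
        r = g.cluster_gmm_auto(X, seed=11)
        assert r.k == 2
        assert g.adjusted_rand_index(r.labels, y) == pytest.approx(1.0)

    def test_bic_table_minimum_matches_choice(self, standardized):
        r = g.cluster_gmm_auto(standardized, seed=17)
        bic = r.diagnostics["bic_by_k"]
        assert r.diagnostics["k_bic"] == min(bic, key=bic.get)

    def test_seeded_determinism(self, standardized):
        a = g.cluster_gmm_auto(standardized, seed=5)
        b = g.cluster_gmm_auto(standardized, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestEpsEstimation:
    def test_uniform_1d_spacing_recovers_common_spacing(self):
        # interior points see their 2nd neighbour at the common spacing; the
        # two ends see it one step further, and the knee lands on the spacing
        X = np.arange(10, dtype=float)[:, None]
        eps = g.estimate_eps_kdistance(X)
        assert eps == pytest.approx(1.0)

    def test_two_tight_clusters_recovered(self):
        # two evenly dense clusters far apart: eps lands on the intra-cluster
        # scale and the eps-neighbourhood graph has two components
        X = np.concatenate([np.arange(0, 1, 0.1), np.arange(50, 51, 0.1)])[:, None]
        eps = g.estimate_eps_kdistance(X)
        assert 0.1 < eps < 50.0
        r = g.cluster_dbscan_auto(X)
        assert r.k == 2

    def test_duplicated_points_still_positive_eps(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        eps = g.estimate_eps_kdistance(X)
        assert np.isfinite(eps) and eps > 0


class TestDBSCANAuto:
    def test_eps_above_max_distance_single_cluster(self, standardized):
        from sklearn.cluster import DBSCAN

        X = standardized.as_array()
        big = float(np.linalg.norm(X.max(0) - X.min(0))) + 1
        labels = DBSCAN(eps=big, min_samples=1).fit(X).labels_
        assert len(np.unique(labels)) == 1

    def test_eps_below_min_distance_all_singletons(self):
        from sklearn.cluster import DBSCAN

        X = np.arange(8, dtype=float)[:, None]
        labels = DBSCAN(eps=0.5, min_samples=1).fit(X).labels_
        assert len(np.unique(labels)) == 8
        assert (labels >= 0).all()  # min_samples=1: no noise points

    def test_chain_transitivity(self):
        # |AB| = |BC| = 1 <= eps < |AC| = 2 -> one connected component
        from sklearn.cluster import DBSCAN

        X = np.array([[0.0], [1.0], [2.0]])
        labels = DBSCAN(eps=1.0, min_samples=1).fit(X).labels_
        assert len(np.unique(labels)) == 1

    def test_every_sample_labelled_on_panel(self, standardized):
        r = g.cluster_dbscan_auto(standardized)
        assert r.labels.size == 21
        assert (r.labels >= 0).all()


class TestWardAuto:
    def test_three_blobs(self):
        X, y = make_blobs(n_samples=30, centers=3, cluster_std=0.2, random_state=23)
        r = g.cluster_ward_auto(X)
        assert r.k == 3
        assert g.adjusted_rand_index(r.labels, y) == pytest.approx(1.0)

    def test_merge_heights_match_bruteforce_ward_objective(self):
        # independent oracle: greedy merges minimising the ESS increase
        # |A||B|/(|A|+|B|) * ||cA - cB||^2; scipy reports sqrt(2*dESS)
        X = np.array([[0.0], [1.0], [2.0], [3.0]])

        def brute_ward_heights(points):
            clusters = [[p] for p in points.ravel()]
            heights = []
            while len(clusters) > 1:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        a, b = clusters[i], clusters[j]
                        ca, cb = np.mean(a), np.mean(b)
                        d_ess = len(a) * len(b) / (len(a) + len(b)) * (ca - cb) ** 2
                        if best is None or d_ess < best[0]:
                            best = (d_ess, i, j)
                        # ties: scipy merges the first-found minimal pair
                d_ess, i, j = best
                heights.append(np.sqrt(2 * d_ess))
                merged = clusters[i] + clusters[j]
                clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                clusters.append(merged)
            return heights

        expected = brute_ward_heights(X)
        Z = linkage(X, method="ward")
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(expected), atol=1e-12)
        # hand values: two adjacent singleton merges at 1, final at 2*sqrt(2)
        np.testing.assert_allclose(sorted(Z[:, 2]), [1.0, 1.0, 2 * np.sqrt(2)])

    def test_chosen_cut_maximises_silhouette(self, standardized):
        from sklearn.metrics import silhouette_score

        r = g.cluster_ward_auto(standardized)
        sil = r.diagnostics["silhouette_by_k"]
        chosen = silhouette_score(standardized.as_array(), r.labels)
        assert chosen >= max(sil.values()) - 1e-12


class TestSharedInvariants:
    @pytest.mark.parametrize("algo", ["kmeans", "gmm", "dbscan", "ward"])
    def test_every_sample_labelled(self, standardized, algo):
        r = g.cluster_auto(standardized, algorithm=algo, seed=17)
        assert r.labels.size == len(standardized.sample_ids)
        assert r.k == len(np.unique(r.labels))

    @pytest.mark.parametrize("algo", ["kmeans", "gmm", "dbscan", "ward"])
    def test_row_permutation_equivariance(self, standardized, algo):
        X = standardized.as_array()
        rng = np.random.default_rng(99)
        perm = rng.permutation(len(X))
        r1 = g.cluster_auto(X, algorithm=algo, seed=17)
        r2 = g.cluster_auto(X[perm], algorithm=algo, seed=17)
        assert g.adjusted_rand_index(r1.labels[perm], r2.labels) == pytest.approx(1.0)

    def test_default_k_range(self):
        assert default_k_range(21) == (2, 10)
        assert default_k_range(63) == (2, 20)
        assert default_k_range(5) == (2, 4)

    def test_wcss_table_starts_at_one_and_decreases(self, standardized):
        w = wcss_table(standardized, seed=17)
        ks = sorted(w)
        assert ks[0] == 1
        assert all(w[a] >= w[b] - 1e-9 for a, b in zip(ks, ks[1:]))
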