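"""k-means, partition-quality indices, natural-k selection, heatmap layout."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from ffasc.cluster import (
    INFINITE_SEPARATION,
    average_silhouette,
    calinski_harabasz,
    heatmap_order,
    heatmap_transform,
    kmeans_cluster,
    make_heatmap_layout,
    outlier_status,
    select_natural_k,
    _lloyd,
)
from ffasc.errors import ClusteringError
from ffasc.simulate import generate_clustered_species


def brute_silhouette(X, labels):
    """Loop-based silhouette oracle, independent of the vectorized path."""
    n = len(X)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def brute_ch(X, labels):
    """Direct-formula Calinski–Harabasz oracle."""
    n, k = len(X), len(set(labels))
    grand = X.mean(axis=0)
    W = B = 0.0
    for c in set(labels):
        block = X[np.asarray(labels) == c]
        cent = block.mean(axis=0)
        W += ((block - cent) ** 2).sum()
        B += len(block) * ((cent - grand) ** 2).sum()
    return (B / (k - 1)) / (W / (n - k))


class TestKMeans:
    def test_k1_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        a = kmeans_cluster(X, 1, seed=0)
        assert set(a.labels) == {1}

    def test_k_equals_n_singletons(self):
        X = np.random.default_rng(1).normal(size=(7, 3))
        a = kmeans_cluster(X, 7, seed=0)
        assert sorted(a.labels) == list(range(1, 8))
        assert a.inertia == pytest.approx(0.0)

    def test_two_blobs_exactly_recovered(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (12, 4)), rng.normal(10, 0.3, (15, 4))])
        a = kmeans_cluster(X, 2, seed=3)
        left, right = set(a.labels[:12]), set(a.labels[12:])
        assert len(left) == len(right) == 1 and left != right

    def test_k_above_n_rejected(self):
        with pytest.raises(ClusteringError):
            kmeans_cluster(np.zeros((3, 2)), 4, seed=0)

    def test_lloyd_inertia_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        _, _, trace = _lloyd(X, X[rng.choice(40, 6, replace=False)].copy())
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_matches_sklearn_objective_on_blobs(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(c * 8, 1.0, (20, 6)) for c in range(3)])
        ours = kmeans_cluster(X, 3, seed=6)
        ref = KMeans(3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        X = np.array([[0.0, 0], [0.1, 0], [50, 0], [50.1, 0]])
        labels = np.array([1, 1, 2, 2])
        val = average_silhouette(X, labels)
        assert val > 0.9
        assert val == pytest.approx(brute_silhouette(X, labels), abs=1e-9)

    def test_all_identical_points_zero_by_convention(self):
        X = np.zeros((6, 3))
        assert average_silhouette(X, np.array([1, 1, 1, 2, 2, 2])) == 0.0

    def test_singleton_cluster_contributes_zero(self):
        X = np.array([[0.0], [1.0], [10.0]])
        labels = np.array([1, 1, 2])
        assert average_silhouette(X, labels) == pytest.approx(
            brute_silhouette(X, labels), abs=1e-12
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ClusteringError):
            average_silhouette(np.zeros((4, 2)), np.array([1, 1, 1, 1]))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        k = int(rng.integers(2, min(5, n)))
        X = rng.normal(size=(n, 4))
        labels = rng.integers(1, k + 1, n)
        labels[:k] = np.arange(1, k + 1)  # every cluster nonempty
        ours = average_silhouette(X, labels)
        assert ours == pytest.approx(brute_silhouette(X, labels), abs=1e-9)
        assert ours == pytest.approx(silhouette_score(X, labels), abs=1e-9)
        assert -1.0 <= ours <= 1.0


class TestCalinskiHarabasz:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_oracles(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 30))
        k = int(rng.integers(2, min(6, n - 1)))
        X = rng.normal(size=(n, 3))
        labels = rng.integers(1, k + 1, n)
        labels[:k] = np.arange(1, k + 1)
        ours = calinski_harabasz(X, labels)
        assert ours == pytest.approx(brute_ch(X, labels), abs=1e-9)
        assert ours == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-9)

    def test_grows_with_separation(self):
        vals = []
        for gap in (2.0, 5.0, 10.0):
            X = np.array([[0, 0], [1, 0], [gap, 0], [gap + 1, 0.0]])
            vals.append(calinski_harabasz(X, np.array([1, 1, 2, 2])))
        assert vals[0] < vals[1] < vals[2]

    def test_zero_within_scatter_sentinel(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        assert calinski_harabasz(X, np.array([1, 1, 2, 2])) == INFINITE_SEPARATION


class TestNaturalK:
    def test_paper_like_layout_selects_planted_k(self):
        """Five blobs plus a 3-member outgroup: the outgroup is mixed at
        small k, exclusive at the planted k=6, and splits beyond."""
        matrix, _, outlier_ids = generate_clustered_species(
            k=5, cluster_sizes=25, n_outliers=3, seed=0
        )
        report = select_natural_k(matrix, outlier_ids, 2, 10, seed=0)
        assert report.selected_k == 6
        assert 6 in report.candidate_ks
        statuses = {r.k: r.outlier_status for r in report.records}
        assert statuses[6] == "exclusive_together"
        assert any(s == "split" for k, s in statuses.items() if k > 6)
        for r in report.records:
            assert -1.0 <= r.avg_silhouette <= 1.0

    def test_identical_distant_outliers_exclusive_at_k2(self):
        rng = np.random.default_rng(1)
        ingroup = rng.normal(0, 1, (20, 4))
        outliers = np.tile([100.0, 100, 100, 100], (3, 1))
        matrix = pd.DataFrame(
            np.vstack([ingroup, outliers]),
            index=[f"s{i}" for i in range(20)] + ["o1", "o2", "o3"],
        )
        report = select_natural_k(matrix, ["o1", "o2", "o3"], 2, 4, seed=1)
        assert report.records[0].k == 2
        assert report.records[0].outlier_status == "exclusive_together"

    def test_statuses_internally_consistent_on_unstructured_data(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.normal(size=(25, 5)), index=[f"s{i}" for i in range(25)]
        )
        report = select_natural_k(matrix, ["s0", "s1"], 2, 8, seed=2)
        assert len(report.records) == 7
        if report.selected_k is not None:
            assert report.selected_k in report.candidate_ks
            first_together = min(
                r.k for r in report.records if r.outlier_status == "exclusive_together"
            )
            assert report.candidate_ks[0] == first_together

    def test_missing_outliers_rejected(self):
        matrix = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"))
        with pytest.raises(ClusteringError):
            select_natural_k(matrix, ["ghost"], 2, 3)

    def test_status_classifier(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        # outgroup alone in cluster 3
        assert outlier_status(labels, np.array([0, 0, 0, 0, 1, 1])) == "exclusive_together"
        # outgroup shares cluster 2 with an in-group point
        assert outlier_status(np.array([1, 1, 2, 2, 2, 3]), np.array([0, 0, 1, 1, 0, 0])) == "mixed"
        # outgroup spans clusters 1 and 3
        assert outlier_status(labels, np.array([0, 1, 0, 0, 0, 1])) == "split"


class TestHeatmap:
    def test_noise_bounded_and_deterministic(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(6, 5))
        t1 = heatmap_transform(M, seed=11)
        t2 = heatmap_transform(M, seed=11)
        np.testing.assert_array_equal(t1, t2)
        assert np.abs(t1 - M).max() <= 0.5e-10

    def test_zero_matrix_noise_range(self):
        t = heatmap_transform(np.zeros((4, 4)), seed=0)
        assert np.all(t >= -0.5e-10) and np.all(t <= 0.5e-10)

    def test_orders_are_permutations(self):
        rng = np.random.default_rng(4)
        layout = heatmap_order(rng.normal(size=(2, 2)))
        assert sorted(layout.row_order) == [0, 1]
        assert sorted(layout.column_order) == [0, 1]

    def test_duplicate_rows_adjacent(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(5, 8))
        M = np.vstack([base, base[2]])  # row 5 duplicates row 2
        order = list(heatmap_order(M).row_order)
        assert abs(order.index(2) - order.index(5)) == 1

    def test_linkage_heights_match_scipy_average_oracle(self):
        """The leaf order comes from scipy average linkage on the same
        Spearman distances a brute-force computation yields."""
        rng = np.random.default_rng(6)
        M = rng.normal(size=(7, 9))
        from ffasc.cluster import _spearman_linkage_order, _zscore
        from scipy.stats import spearmanr

        Z = _zscore(_zscore(M, axis=1), axis=0)
        n = Z.shape[0]
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                rho = spearmanr(Z[i], Z[j]).statistic
                dist[i, j] = dist[j, i] = 1 - rho
        expected = average(squareform(dist, checks=False))
        from scipy.cluster.hierarchy import leaves_list

        np.testing.assert_array_equal(
            _spearman_linkage_order(Z), leaves_list(expected)
        )

    def test_constant_row_warns(self):
        from ffasc.cluster import _spearman_linkage_order

        Z = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0)[::-1]])
        with pytest.warns(UserWarning, match="constant"):
            _spearman_linkage_order(Z)

    def test_layout_combines_transform_and_order(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(5, 6))
        layout = make_heatmap_layout(M, seed=9)
        assert np.abs(layout.transformed_matrix - M).max() <= 0.5e-10
        assert sorted(layout.row_order) == list(range(5))
        assert sorted(layout.column_order) == list(range(6))
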