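import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenoclust as pc
from phenoclust.distances import euclidean_distances

from conftest import assignment, make_binary


class TestAggregateScores:
    def test_upper_bound_and_zero_row(self):
        bm = make_binary([[1] * 5, [0] * 5])
        items = assignment([1, 1, 1, 2, 2],
                           labels=[f"x{j}" for j in range(5)])
        scores = pc.aggregate_cluster_scores(bm, items)
        assert scores.data.iloc[0].tolist() == [3, 2]
        assert scores.data.iloc[1].tolist() == [0, 0]
        assert scores.item_counts == {"C1": 3, "C2": 2}

    def test_singleton_clusters_reproduce_matrix(self):
        bm = make_binary([[1, 0], [0, 1]])
        items = assignment([1, 2], labels=["x0", "x1"])
        scores = pc.aggregate_cluster_scores(bm, items)
        assert np.array_equal(scores.values(), bm.values())

    def test_unassigned_item_rejected(self):
        bm = make_binary([[1, 0], [0, 1]])
        items = assignment([1], labels=["x0"])
        with pytest.raises(ValueError, match="x1"):
            pc.aggregate_cluster_scores(bm, items)


def exhaustive_best_within_ss(x, k=2):
    """Best k=2 partition by within-SS, by enumerating all bipartitions."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + bits)
        if labels.max() == 0:
            continue
        within = 0.0
        for c in (0, 1):
            sub = x[labels == c]
            if len(sub):
                within += ((sub - sub.mean(axis=0)) ** 2).sum()
        best = min(best, within)
    return best


class TestKmeans:
    def test_two_gap_1d_example(self):
        x = np.array([[0.0], [1.0], [9.0], [10.0]])
        ca, centroids, q = pc.kmeans(x, 2, seed=0)
        assert ca.cluster_ids.tolist() == [1, 1, 2, 2]
        assert sorted(c[0] for c in centroids) == [0.5, 9.5]
        assert q.within_ss == pytest.approx(1.0)
        assert q.bt_ratio == pytest.approx(81 / 82)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_partition(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(int(rng.integers(5, 11)), 2))
        _, _, q = pc.kmeans(x, 2, n_init=20, seed=seed)
        assert q.within_ss == pytest.approx(exhaustive_best_within_ss(x),
                                            rel=1e-9)

    def test_k_distinct_locations(self):
        x = np.repeat(np.array([[0.0], [5.0], [9.0]]), 3, axis=0)
        _, _, q = pc.kmeans(x, 3, seed=1)
        assert q.within_ss == pytest.approx(0.0)
        assert q.bt_ratio == pytest.approx(1.0)

    def test_duplicate_rows_degenerate(self):
        x = np.ones((6, 2))
        _, _, q = pc.kmeans(x, 2, seed=0)
        assert q.within_ss == pytest.approx(0.0)
        assert q.bt_ratio == 0.0  # zero total SS convention

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 3))
        a = pc.kmeans(x, 4, seed=7)
        b = pc.kmeans(x, 4, seed=7)
        assert a[0].cluster_ids.tolist() == b[0].cluster_ids.tolist()
        assert np.allclose(a[1], b[1])

    def test_not_worse_than_sklearn(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(c, 0.5, size=(30, 2)) for c in (0, 4, 8)])
        _, _, q = pc.kmeans(x, 3, n_init=10, seed=0)
        ref = sklearn_cluster.KMeans(3, n_init=10, random_state=0).fit(x)
        assert q.within_ss <= ref.inertia_ * (1 + 1e-9)

    def test_standardize_flag(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 2)) * np.array([100.0, 0.01])
        _, _, q = pc.kmeans(x, 2, seed=0, standardize=True)
        assert q.total_ss == pytest.approx(80.0)  # n*d after z-scoring

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            pc.kmeans(np.zeros((3, 2)), 1, seed=0)
        with pytest.raises(ValueError):
            pc.kmeans(np.zeros((3, 2)), 3, seed=0)


class TestPam:
    def test_two_tight_groups_exhaustive(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))])
        dm = euclidean_distances(x)
        res = pc.pam(dm, 2, seed=0)
        # oracle: enumerate every medoid pair and minimize assignment cost
        best_cost, best_pair = np.inf, None
        for pair in itertools.combinations(range(6), 2):
            cost = dm.values[:, pair].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_pair = cost, set(pair)
        assert set(res.medoid_indices) == best_pair
        assert res.cost == pytest.approx(best_cost)
        assert res.assignment.cluster_ids.tolist() == [1, 1, 1, 2, 2, 2]

    def test_k_equals_n(self):
        x = np.arange(4, dtype=float)[:, None]
        res = pc.pam(euclidean_distances(x), 4, seed=0)
        assert res.cost == pytest.approx(0.0)
        assert len(res.medoids) == 4

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        dm = euclidean_distances(x)
        a, b = pc.pam(dm, 3, seed=5), pc.pam(dm, 3, seed=5)
        assert a.medoids == b.medoids

    def test_k_exceeding_n(self):
        with pytest.raises(ValueError):
            pc.pam(euclidean_distances(np.zeros((2, 1))), 3)


class TestSilhouette:
    def test_hand_example(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        dm = euclidean_distances(x, [f"p{i}" for i in range(4)])
        s, mean = pc.silhouette(assignment([1, 1, 2, 2]), dm)
        assert s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-9)
        assert mean == pytest.approx(s.mean())

    def test_identical_points_convention(self):
        dm = euclidean_distances(np.zeros((4, 1)), [f"p{i}" for i in range(4)])
        s, mean = pc.silhouette(assignment([1, 1, 2, 2]), dm)
        assert (s == 0).all() and mean == 0.0

    def test_singleton_gets_zero(self):
        x = np.array([[0.0], [0.1], [9.0]])
        s, _ = pc.silhouette(assignment([1, 1, 2]),
                             euclidean_distances(x, ["p0", "p1", "p2"]))
        assert s[2] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            pc.silhouette(assignment([1, 1]),
                          euclidean_distances(np.zeros((2, 1)), ["p0", "p1"]))

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 3))
        ids = rng.integers(1, 4, size=40)
        while len(np.unique(ids)) < 3 or (np.bincount(ids)[1:] == 1).any():
            ids = rng.integers(1, 4, size=40)
        ca = assignment(ids, labels=list(range(40)))
        _, mean = pc.silhouette(ca, euclidean_distances(x, list(range(40))))
        ref = sklearn_metrics.silhouette_score(x, ca.cluster_ids)
        assert mean == pytest.approx(ref, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_range_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 2))
        ids = rng.integers(1, 4, size=20)
        if len(np.unique(ids)) < 2:
            ids[0] = 1 + (ids[0] % 3)
            ids[1] = 1 + ((ids[0]) % 3)
        from phenoclust.hierarchy import relabel_by_first_appearance

        ca = relabel_by_first_appearance(ids, list(range(20)))
        if ca.k < 2:
            return
        s, _ = pc.silhouette(ca, euclidean_distances(x, list(range(20))))
        assert (s >= -1 - 1e-12).all() and (s <= 1 + 1e-12).all()

    def test_random_labels_on_noise_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(500, 3))
        ids = rng.integers(1, 4, size=500)
        from phenoclust.hierarchy import relabel_by_first_appearance

        ca = relabel_by_first_appearance(ids, list(range(500)))
        _, mean = pc.silhouette(ca, euclidean_distances(x, list(range(500))))
        assert abs(mean) < 0.1


class TestSSDecomposition:
    def test_perfect_separation(self):
        q = pc.ss_decomposition(np.array([0.0, 0, 10, 10])[:, None],
                                assignment([1, 1, 2, 2]))
        assert q.within_ss == pytest.approx(0.0)
        assert q.total_ss == pytest.approx(100.0)
        assert q.bt_ratio == pytest.approx(1.0)

    def test_single_cluster(self):
        q = pc.ss_decomposition(np.arange(4.0)[:, None], assignment([1, 1, 1, 1]))
        assert q.between_ss == pytest.approx(0.0)
        assert q.bt_ratio == 0.0

    def test_hand_decomposition(self):
        # {0,1,9,10} split {0,1}/{9,10}: within 1.0, total 82, ratio 81/82
        q = pc.ss_decomposition(np.array([0.0, 1, 9, 10])[:, None],
                                assignment([1, 1, 2, 2]))
        assert q.within_ss == pytest.approx(1.0)
        assert q.total_ss == pytest.approx(82.0)
        assert q.bt_ratio == pytest.approx(81 / 82)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_within_plus_between_equals_total(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.normal(size=(n, int(rng.integers(1, 5))))
        ids = rng.integers(1, 4, size=n)
        from phenoclust.hierarchy import relabel_by_first_appearance

        ca = relabel_by_first_appearance(ids, list(range(n)))
        q = pc.ss_decomposition(x, ca)
        assert q.within_ss + q.between_ss == pytest.approx(q.total_ss,
                                                           rel=1e-9)
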