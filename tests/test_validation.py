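import itertools

import numpy as np
import pandas as pd
import pytest

import phenoclust as pc
from phenoclust.partition import ScoreMatrix

from conftest import assignment, make_binary


class TestRandomAssignmentNull:
    def test_empirical_p_formula_edge(self, discovery_small):
        bm, _ = discovery_small
        inputs = pc.prepare_inputs(bm)
        observed = pc.cut(inputs.item_dendro, 3)
        null = pc.random_assignment_null(bm, observed, k_p=4, B=1, seed=0)
        assert null.empirical_p in (0.5, 1.0)

    def test_empirical_p_matches_formula(self, discovery_small):
        bm, _ = discovery_small
        inputs = pc.prepare_inputs(bm)
        observed = pc.cut(inputs.item_dendro, 3)
        null = pc.random_assignment_null(bm, observed, k_p=4, B=19, seed=1)
        expected = (1 + sum(d >= null.observed for d in null.draws)) / 20
        assert null.empirical_p == pytest.approx(expected, abs=1e-12)

    def test_planted_structure_beats_null(self, discovery_small):
        bm, _ = discovery_small
        inputs = pc.prepare_inputs(bm)
        observed = pc.cut(inputs.item_dendro, 3)
        null = pc.random_assignment_null(bm, observed, k_p=4, B=99, seed=7)
        assert null.observed > null.percentile(95)
        assert null.empirical_p == pytest.approx(1 / 100)

    def test_structureless_data_not_extreme(self):
        cfg = pc.preset("noise", n_participants=400)
        rm, _ = pc.generate_cohort(cfg, seed=0)
        bm = pc.binarize(rm)
        inputs = pc.prepare_inputs(bm)
        observed = pc.cut(inputs.item_dendro, 3)
        null = pc.random_assignment_null(bm, observed, k_p=4, B=49, seed=0)
        assert null.empirical_p > 0.05

    def test_size_profile_preserved(self, discovery_small):
        bm, _ = discovery_small
        from phenoclust.validation import _random_sized_assignment

        rng = np.random.default_rng(0)
        sizes = np.array([19, 12, 12])
        ra = _random_sized_assignment(list(bm.data.columns), sizes, rng)
        assert sorted(ra.sizes().tolist()) == sorted(sizes.tolist())

    def test_b_validation(self, discovery_small):
        bm, _ = discovery_small
        observed = assignment([1] * 21 + [2] * 22,
                              labels=list(bm.data.columns))
        with pytest.raises(ValueError):
            pc.random_assignment_null(bm, observed, k_p=4, B=0)


class TestBootstrapStability:
    def test_planted_items_co_cluster(self, discovery_small):
        bm, truth = discovery_small
        freq = pc.bootstrap_item_stability(bm, k_i=3, B=30, seed=11)
        labels = truth.item_cluster_labels
        within = []
        for i, j in itertools.combinations(range(len(labels)), 2):
            if labels[i] == labels[j]:
                within.append(freq.iloc[i, j])
        assert np.nanmean(within) >= 0.8

    def test_diagonal_is_one_and_frequencies_valid(self, discovery_small):
        bm, _ = discovery_small
        freq = pc.bootstrap_item_stability(bm, k_i=3, B=5, seed=2)
        assert np.allclose(np.diag(freq.to_numpy()), 1.0)
        vals = freq.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert (finite >= 0).all() and (finite <= 1).all()

    def test_two_draws_give_quantized_frequencies(self):
        bm = make_binary(np.tile([[1, 1, 0, 0], [0, 0, 1, 1]], (10, 1)))
        freq = pc.bootstrap_item_stability(bm, k_i=2, B=2, seed=3)
        off_diag = freq.to_numpy()[~np.eye(4, dtype=bool)]
        assert set(np.round(off_diag[np.isfinite(off_diag)], 6)) <= {0.0, 0.5, 1.0}

    def test_b_validation(self, discovery_small):
        bm, _ = discovery_small
        with pytest.raises(ValueError):
            pc.bootstrap_item_stability(bm, k_i=3, B=1)


def brute_force_ari(a_ids, b_ids):
    """ARI via the permutation expectation of the Rand index.

    RI is computed over all pair agreements; its null expectation is the
    average over every relabeling (permutation) of one partition's entity
    order.  ARI = (RI - E[RI]) / (max RI - E[RI]).
    """
    a_ids, b_ids = np.asarray(a_ids), np.asarray(b_ids)
    n = len(a_ids)
    pairs = list(itertools.combinations(range(n), 2))

    def rand(b):
        agree = sum(
            (a_ids[i] == a_ids[j]) == (b[i] == b[j]) for i, j in pairs
        )
        return agree / len(pairs)

    ri = rand(b_ids)
    perms = [rand(b_ids[list(p)]) for p in itertools.permutations(range(n))]
    expected = float(np.mean(perms))
    if abs(1.0 - expected) < 1e-15:
        return 0.0
    return (ri - expected) / (1.0 - expected)


class TestAdjustedRand:
    def test_identical_partitions(self):
        a = assignment([1, 1, 2, 2, 3])
        assert pc.adjusted_rand(a, a) == pytest.approx(1.0)

    def test_hand_contingency_example(self):
        a = assignment([1, 1, 2, 2])
        b = assignment([1, 2, 1, 2])
        assert pc.adjusted_rand(a, b) == pytest.approx(-0.5)

    def test_degenerate_convention(self):
        a = assignment([1, 2, 3, 4])     # all singletons
        b = assignment([1, 1, 1, 1])     # one cluster
        assert pc.adjusted_rand(a, b) == 0.0

    def test_label_order_independent(self):
        a = assignment([1, 1, 2, 2], labels=["w", "x", "y", "z"])
        b = assignment([1, 2, 2, 1], labels=["y", "z", "w", "x"])
        # b in a's order is (2 -> w, 1 -> x? ...) -- mapping by shared labels
        aligned = pc.adjusted_rand(a, b)
        b2 = assignment([2, 1, 1, 2], labels=["w", "x", "y", "z"])
        assert aligned == pytest.approx(pc.adjusted_rand(a, b2))

    def test_disjoint_entity_sets_rejected(self):
        a = assignment([1, 2], labels=["a", "b"])
        b = assignment([1, 2], labels=["c", "d"])
        with pytest.raises(ValueError):
            pc.adjusted_rand(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_permutation_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        a_ids = rng.integers(1, 4, size=n)
        b_ids = rng.integers(1, 4, size=n)
        from phenoclust.hierarchy import relabel_by_first_appearance

        a = relabel_by_first_appearance(a_ids, list(range(n)))
        b = relabel_by_first_appearance(b_ids, list(range(n)))
        assert pc.adjusted_rand(a, b) == pytest.approx(
            brute_force_ari(a.cluster_ids, b.cluster_ids), abs=1e-9
        )

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(21)
        a_ids = rng.integers(1, 5, size=60)
        b_ids = rng.integers(1, 5, size=60)
        from phenoclust.hierarchy import relabel_by_first_appearance

        a = relabel_by_first_appearance(a_ids, list(range(60)))
        b = relabel_by_first_appearance(b_ids, list(range(60)))
        assert pc.adjusted_rand(a, b) == pytest.approx(
            sklearn_metrics.adjusted_rand_score(a_ids, b_ids), abs=1e-12
        )


def _score_matrix(cols: dict, counts: dict) -> ScoreMatrix:
    df = pd.DataFrame(cols)
    df.index = [f"p{i}" for i in range(len(df))]
    return ScoreMatrix(df, counts)


class TestNormalizedMad:
    def test_hand_examples(self):
        sm = _score_matrix({"C1": [0, 1, 2, 3, 4]}, {"C1": 10})
        disp = pc.normalized_mad(sm)
        assert disp.normalized_mad["C1"] == pytest.approx(0.1)

    def test_constant_column(self):
        sm = _score_matrix({"C1": [2, 2, 2, 2]}, {"C1": 5})
        assert pc.normalized_mad(sm).normalized_mad["C1"] == 0.0

    def test_half_half_extreme(self):
        sm = _score_matrix({"C1": [0, 0, 8, 8]}, {"C1": 8})
        assert pc.normalized_mad(sm).normalized_mad["C1"] == pytest.approx(0.5)

    def test_consistency_constant_flag(self):
        sm = _score_matrix({"C1": [0, 1, 2, 3, 4]}, {"C1": 10})
        disp = pc.normalized_mad(sm, consistency_constant=True)
        assert disp.normalized_mad["C1"] == pytest.approx(0.14826)


class TestSpearman:
    def test_monotone_and_antitone(self):
        sm = _score_matrix(
            {"C1": [0, 1, 2, 3, 5], "C2": [1, 2, 4, 8, 9],
             "C3": [9, 8, 4, 2, 1]},
            {"C1": 10, "C2": 10, "C3": 10},
        )
        rho = pc.spearman_matrix(sm)["overall"]
        assert rho.loc["C1", "C2"] == pytest.approx(1.0)
        assert rho.loc["C1", "C3"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            r = np.random.default_rng(seed)
            sm = _score_matrix(
                {"C1": r.integers(0, 10, 1000), "C2": r.integers(0, 10, 1000)},
                {"C1": 10, "C2": 10},
            )
            rho = pc.spearman_matrix(sm)["overall"]
            assert abs(rho.loc["C1", "C2"]) < 0.1

    def test_by_group_strata(self, discovery_small):
        bm, truth = discovery_small
        inputs = pc.prepare_inputs(bm)
        scores = pc.aggregate_cluster_scores(bm, pc.cut(inputs.item_dendro, 3))
        groups = assignment(truth.participant_group_labels,
                            labels=list(scores.data.index))
        result = pc.spearman_matrix(scores, groups)
        assert set(result["by_group"]) == set(range(1, groups.k + 1))
        for df in result["by_group"].values():
            vals = df.to_numpy()
            finite = vals[np.isfinite(vals)]
            assert (np.abs(finite) <= 1 + 1e-12).all()

    def test_small_stratum_rejected(self):
        sm = _score_matrix({"C1": [0, 1], "C2": [1, 0]}, {"C1": 5, "C2": 5})
        with pytest.raises(ValueError):
            pc.spearman_matrix(sm)
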