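import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import oracles
from bsnmf.partition import Partition
from bsnmf.validity import (
    accuracy,
    adjusted_rand,
    average_silhouette,
    comembership_matrix,
    cophenetic_pearson,
    dunn_index,
    gap_statistic,
    homogeneity,
    hubert_gamma,
    pairwise_distances,
    separation,
    within_dispersion,
)


def _make(labels):
    labels = np.asarray(labels, int)
    return Partition([str(i) for i in range(len(labels))], labels,
                     int(labels.max()))


def _random_instance(rng, n=None, k=None, f=4):
    n = n or int(rng.integers(8, 20))
    k = k or int(rng.integers(2, 5))
    X = rng.random((n, f)) * 5
    labels = oracles.random_partition(rng, n, k)
    return X, pairwise_distances(X), labels


class TestHomogeneity:
    def test_identical_items_per_cluster_give_one(self):
        X = np.array([[1.0, 2, 3]] * 3 + [[5.0, 1, 2]] * 2)
        p = _make([1, 1, 1, 2, 2])
        assert homogeneity(X, p) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_loop(self, rng):
        for _ in range(10):
            X, _, labels = _random_instance(rng, f=5)
            assert homogeneity(X, _make(labels)) == pytest.approx(
                oracles.homogeneity_loop(X, labels), abs=1e-10
            )

    def test_constant_profile_contributes_zero(self):
        X = np.array([[1.0, 2], [1.0, 2], [3.0, 3]])
        p = _make([1, 1, 2])
        # third item is its own cluster with a flat profile: contributes 0
        assert homogeneity(X, p) == pytest.approx(2 / 3, abs=1e-12)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match="feature"):
            homogeneity(np.ones((4, 1)), _make([1, 1, 2, 2]))


class TestSeparationAndDunn:
    def test_two_interval_example(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = pairwise_distances(X)
        p = _make([1, 1, 2, 2])
        assert separation(D, p) == pytest.approx(9.0)
        assert dunn_index(D, p) == pytest.approx(9.0)

    def test_coincident_boundary_points_give_zero_separation(self):
        X = np.array([[0.0], [5.0], [5.0], [9.0]])
        p = _make([1, 1, 2, 2])
        assert separation(pairwise_distances(X), p) == 0.0

    def test_all_singletons_dunn_is_infinite(self):
        X = np.array([[0.0], [1.0], [5.0]])
        p = _make([1, 2, 3])
        assert dunn_index(pairwise_distances(X), p) == math.inf

    def test_match_brute_force_loops(self, rng):
        for _ in range(10):
            X, D, labels = _random_instance(rng)
            p = _make(labels)
            assert separation(D, p) == pytest.approx(
                oracles.separation_loop(D.values, labels), abs=1e-10)
            assert dunn_index(D, p) == pytest.approx(
                oracles.dunn_loop(D.values, labels), abs=1e-10)

    def test_single_cluster_rejected(self):
        D = pairwise_distances(np.arange(4.0).reshape(-1, 1))
        with pytest.raises(ValueError):
            separation(D, _make([1, 1, 1, 1]))
        with pytest.raises(ValueError):
            dunn_index(D, _make([1, 1, 1, 1]))


class TestSilhouette:
    def test_perfectly_separated_duplicates(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        p = _make([1, 1, 2, 2])
        assert average_silhouette(pairwise_distances(X), p) == pytest.approx(1.0)

    def test_hand_computed_three_point_example(self):
        # points 0,1,5 in clusters {0,1},{5}: s = (0.8, 0.75, 0)
        X = np.array([[0.0], [1.0], [5.0]])
        p = _make([1, 1, 2])
        expected = (0.8 + 0.75 + 0.0) / 3
        assert average_silhouette(pairwise_distances(X), p) == pytest.approx(
            expected, abs=1e-12)

    def test_all_points_coincident_gives_zero(self):
        X = np.zeros((4, 2))
        p = _make([1, 1, 2, 2])
        assert average_silhouette(pairwise_distances(X), p) == 0.0

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(10):
            X, D, labels = _random_instance(rng)
            p = _make(labels)
            ours = average_silhouette(D, p)
            assert ours == pytest.approx(
                oracles.silhouette_loop(D.values, labels), abs=1e-10)
            if min(np.bincount(labels)[1:]) > 1:  # sklearn: no singletons
                assert ours == pytest.approx(
                    silhouette_score(X, labels), abs=1e-10)


class TestComembershipAndCophenetic:
    def test_comembership_codes_zero_same_one_different(self):
        C = comembership_matrix(_make([1, 1, 2])).values
        assert C[0, 1] == 0 and C[0, 2] == 1 and C[1, 2] == 1

    def test_perfect_two_valued_alignment_gives_exactly_one(self):
        D = np.array(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], float
        )
        assert cophenetic_pearson(_make([1, 1, 2, 2]), D) == pytest.approx(
            1.0, abs=1e-12)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(10):
            X, D, labels = _random_instance(rng, n=12)
            assert cophenetic_pearson(_make(labels), D) == pytest.approx(
                oracles.cophenetic_loop(D.values, labels), abs=1e-10)

    def test_invariant_to_cluster_relabeling(self, rng):
        X, D, labels = _random_instance(rng, n=10, k=3)
        swapped = np.choose(labels - 1, [2, 3, 1])
        assert cophenetic_pearson(_make(labels), D) == pytest.approx(
            cophenetic_pearson(_make(swapped), D), abs=1e-12)

    def test_degenerate_partitions_rejected(self):
        D = pairwise_distances(np.arange(4.0).reshape(-1, 1))
        with pytest.raises(ValueError):
            cophenetic_pearson(_make([1, 1, 1, 1]), D)
        with pytest.raises(ValueError):
            cophenetic_pearson(_make([1, 2, 3, 4]), D)


class TestHubertGamma:
    def test_tight_far_clusters_score_high(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.05, (8, 2)),
                       rng.normal(20, 0.05, (8, 2))])
        labels = np.array([1] * 8 + [2] * 8)
        D = pairwise_distances(X)
        assert hubert_gamma(_make(labels), D, X) > 0.9

    def test_matches_pair_enumeration(self, rng):
        for _ in range(10):
            X, D, labels = _random_instance(rng, n=12, k=3)
            assert hubert_gamma(_make(labels), D, X) == pytest.approx(
                oracles.hubert_loop(X, D.values, labels), abs=1e-10)

    def test_single_cluster_rejected(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(ValueError):
            hubert_gamma(_make([1] * 5), pairwise_distances(X), X)


class TestGapStatistic:
    def test_one_dimensional_dispersion_contribution(self):
        # cluster {0, 2}: pairwise squared sum / (2 n) = 2*4/(2*2) = 2,
        # which equals the within-cluster sum of squares about the mean
        X = np.array([[0.0], [2.0]])
        p = _make([1, 1])
        assert within_dispersion(X, p) == pytest.approx(2.0)

    def test_dispersion_matches_brute_force(self, rng):
        X, _, labels = _random_instance(rng)
        assert within_dispersion(X, _make(labels)) == pytest.approx(
            oracles.within_dispersion_loop(X, labels), abs=1e-10)

    def test_all_singletons_rejected(self, rng):
        X = rng.random((4, 2))
        with pytest.raises(ValueError, match="singleton|zero"):
            gap_statistic(X, _make([1, 2, 3, 4]), B=10, seed=0)

    def test_uniform_data_at_k1_has_small_gap(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (40, 1))
        p = _make([1] * 40)
        gap, se = gap_statistic(X, p, K=1, B=50, seed=3,
                                clusterer=lambda d, k, s: _make([1] * len(d)))
        assert abs(gap) <= 3 * se

    def test_degenerate_constant_data_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gap_statistic(np.ones((5, 2)), _make([1, 1, 2, 2, 2]), B=10, seed=0)


class TestAdjustedRand:
    def test_identical_groupings_score_one(self, rng):
        labels = oracles.random_partition(rng, 12, 3)
        relabeled = np.choose(labels - 1, [3, 1, 2])
        assert adjusted_rand(_make(labels), _make(relabeled)) == pytest.approx(1.0)

    def test_crossing_partition_scores_minus_half(self):
        a = _make([1, 1, 2, 2])
        b = _make([1, 2, 1, 2])
        assert adjusted_rand(a, b) == pytest.approx(-0.5)

    def test_matches_pair_counting_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            la = oracles.random_partition(rng, n, int(rng.integers(2, 5)))
            lb = oracles.random_partition(rng, n, int(rng.integers(2, 5)))
            ours = adjusted_rand(_make(la), _make(lb))
            assert ours == pytest.approx(oracles.ari_pairs(la, lb), abs=1e-10)
            assert ours == pytest.approx(adjusted_rand_score(la, lb), abs=1e-10)

    def test_symmetric_in_arguments(self, rng):
        la = oracles.random_partition(rng, 15, 3)
        lb = oracles.random_partition(rng, 15, 4)
        assert adjusted_rand(_make(la), _make(lb)) == pytest.approx(
            adjusted_rand(_make(lb), _make(la)), abs=1e-12)

    def test_independent_random_partitions_average_near_zero(self, rng):
        vals = []
        for _ in range(200):
            la = oracles.random_partition(rng, 50, 3)
            lb = oracles.random_partition(rng, 50, 3)
            vals.append(adjusted_rand(_make(la), _make(lb)))
        assert abs(np.mean(vals)) <= 0.05


class TestAccuracy:
    def test_perfect_prediction(self):
        truth = {str(i): c for i, c in enumerate("AABB")}
        assert accuracy(_make([2, 2, 1, 1]), truth) == 1.0

    def test_partial_match_example(self):
        truth = {str(i): c for i, c in enumerate("AABB")}
        assert accuracy(_make([1, 1, 1, 2]), truth) == 0.75

    def test_single_cluster_on_balanced_classes(self):
        truth = {str(i): ("A" if i < 5 else "B") for i in range(10)}
        assert accuracy(_make([1] * 10), truth) == 0.5

    def test_single_cluster_prediction_attains_majority_fraction(self, rng):
        # the all-in-one-cluster prediction is always matched to the
        # majority class, so its accuracy equals that class's share
        for _ in range(10):
            n = int(rng.integers(8, 20))
            truth_labels = [f"c{rng.integers(1, 4)}" for _ in range(n)]
            truth = {str(i): c for i, c in enumerate(truth_labels)}
            majority = max(truth_labels.count(c) for c in set(truth_labels)) / n
            assert accuracy(_make([1] * n), truth) == pytest.approx(majority)


class TestPlantedBeatsRandom:
    def test_higher_is_better_indices_favor_planted_partition(self):
        from bsnmf.synthetic import generate_gaussian_clusters

        X, labels = generate_gaussian_clusters(n_per_class=12, n_features=3,
                                               K=3, centers_distance=6,
                                               sigma=1.0, seed=5)
        ids = sorted(labels, key=lambda s: int(s[1:]))
        planted = Partition.from_labels(ids, labels)
        D = pairwise_distances(X)
        rng = np.random.default_rng(9)
        indices = {
            "homogeneity": lambda p: homogeneity(X, p),
            "silhouette": lambda p: average_silhouette(D, p),
            "dunn": lambda p: dunn_index(D, p),
            "cophenetic": lambda p: cophenetic_pearson(p, D),
            "hubert": lambda p: hubert_gamma(p, D, X),
        }
        for name, fn in indices.items():
            planted_val = fn(planted)
            random_vals = []
            for _ in range(20):
                rp = Partition(planted.item_ids,
                               oracles.random_partition(rng, len(ids), 3), 3)
                random_vals.append(fn(rp))
            assert planted_val > np.mean(random_vals), name
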