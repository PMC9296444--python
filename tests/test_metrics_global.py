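import itertools

import numpy as np
import pytest

from dreval import (
    GlobalEvalConfig,
    ParameterError,
    ValidationError,
    centroid_distance_correlation,
    distance_spearman,
    dynamic_k,
    exhaustive_triplet_accuracy,
    knc_preservation,
    random_triplet_accuracy,
)
from dreval.metrics_global import _condensed_to_pair


def enumerate_triplet_accuracy(X, Y):
    """Independent pure-python enumeration of all anchored triplets."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = len(X)
    agree = total = 0
    for i in range(n):
        for j, k in itertools.combinations([p for p in range(n) if p != i], 2):
            sx = np.sign(np.linalg.norm(X[i] - X[j]) - np.linalg.norm(X[i] - X[k]))
            sy = np.sign(np.linalg.norm(Y[i] - Y[j]) - np.linalg.norm(Y[i] - Y[k]))
            agree += sx == sy
            total += 1
    return agree / total


def manual_spearman(a, b):
    """Independent rank-then-Pearson with average ranks."""

    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = avg_rank(a), avg_rank(b)
    return np.corrcoef(ra, rb)[0, 1]


class TestTripletAccuracy:
    def test_similarity_transform_scores_one(self, rng, similarity):
        X = rng.standard_normal((50, 6))
        Y = similarity(rng, 6)(X)
        assert random_triplet_accuracy(X, Y).value == 1.0
        assert exhaustive_triplet_accuracy(X, Y) == 1.0

    def test_reversed_rank_layout_matches_enumeration(self):
        X = np.array([[1.0], [2.0], [4.0], [8.0]])
        Y = np.array([[8.0], [4.0], [2.0], [1.0]])
        expected = enumerate_triplet_accuracy(X, Y)
        assert exhaustive_triplet_accuracy(X, Y) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_matches_independent_enumeration(self, seed):
        r = np.random.default_rng(seed)
        X = r.standard_normal((10, 4))
        Y = r.standard_normal((10, 2))
        assert exhaustive_triplet_accuracy(X, Y) == pytest.approx(
            enumerate_triplet_accuracy(X, Y), abs=1e-15
        )

    def test_sampled_estimator_converges_to_exhaustive(self, rng):
        X = rng.standard_normal((10, 5))
        Y = rng.standard_normal((10, 2))
        truth = exhaustive_triplet_accuracy(X, Y)
        t = 2000
        rep = random_triplet_accuracy(X, Y, GlobalEvalConfig(triplets_per_point=t, seed=0))
        se = np.sqrt(0.25 / (10 * t))
        assert abs(rep.value - truth) < 3 * se

    def test_independent_spaces_score_near_half(self, rng):
        n, t = 300, 5
        X = rng.standard_normal((n, 10))
        Y = rng.standard_normal((n, 2))
        rep = random_triplet_accuracy(X, Y, GlobalEvalConfig(triplets_per_point=t, seed=1))
        assert abs(rep.value - 0.5) < 3 * np.sqrt(0.25 / (n * t))

    def test_single_triplet_endpoints(self):
        X = np.array([[0.0], [1.0], [3.0]])
        assert exhaustive_triplet_accuracy(X, X) == 1.0  # agreeing
        Yrev = np.array([[0.0], [3.0], [4.0]])  # order of d(0,1) vs d(0,2) differs
        val = exhaustive_triplet_accuracy(X, Yrev)
        assert val == pytest.approx(enumerate_triplet_accuracy(X, Yrev))

    def test_guards(self, rng):
        with pytest.raises(ValidationError):
            random_triplet_accuracy(rng.standard_normal((2, 2)), rng.standard_normal((2, 2)))
        with pytest.raises(ParameterError):
            exhaustive_triplet_accuracy(rng.standard_normal((501, 2)),
                                        rng.standard_normal((501, 2)))

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 2))
        cfg = GlobalEvalConfig(seed=9)
        assert (random_triplet_accuracy(X, Y, cfg).value
                == random_triplet_accuracy(X, Y, cfg).value)


class TestDistanceSpearman:
    def test_similarity_transform_scores_one(self, rng, similarity):
        X = rng.standard_normal((30, 5))
        assert distance_spearman(X, similarity(rng, 5)(X)).value == pytest.approx(1.0)

    def test_monotone_distance_map_scores_one(self):
        # a triangle whose three distances are the squares of the original
        # ones: a strictly increasing distance map preserves all ranks
        def triangle(d12, d13, d23):
            x3 = (d12**2 + d13**2 - d23**2) / (2 * d12)
            y3 = np.sqrt(d13**2 - x3**2)
            return np.array([[0.0, 0.0], [d12, 0.0], [x3, y3]])

        X = triangle(3.0, 3.5, 4.0)
        Y = triangle(9.0, 12.25, 16.0)  # squared distances, still a triangle
        assert distance_spearman(X, Y).value == pytest.approx(1.0)

    def test_all_pairs_match_manual_rank_pearson(self, rng):
        X = rng.standard_normal((15, 6))
        Y = rng.standard_normal((15, 2))
        from scipy.spatial.distance import pdist

        expected = manual_spearman(pdist(X), pdist(Y))
        assert distance_spearman(X, Y).value == pytest.approx(expected, abs=1e-12)

    def test_sampled_pairs_match_manual_on_selected_pairs(self, rng):
        n = 60
        X = rng.standard_normal((n, 8))
        Y = rng.standard_normal((n, 2))
        cfg = GlobalEvalConfig(pairs_sample_size=200, seed=4)
        rep = distance_spearman(X, Y, cfg)
        sel = np.random.default_rng(4).choice(n * (n - 1) // 2, 200, replace=False)
        i, j = _condensed_to_pair(sel, n)
        dx = np.linalg.norm(X[i] - X[j], axis=1)
        dy = np.linalg.norm(Y[i] - Y[j], axis=1)
        assert rep.value == pytest.approx(manual_spearman(dx, dy), abs=1e-12)
        assert rep.params["pairs_used"] == 200

    def test_constant_distances_flagged_undefined(self):
        X = np.array([[0.0], [1.0], [2.0]])
        Y = np.zeros((3, 2))  # coincident points: all embedding distances 0
        rep = distance_spearman(X, Y)
        assert np.isnan(rep.value) and "undefined" in rep.params

    @pytest.mark.parametrize("n", [5, 20, 100])
    def test_condensed_index_decoding(self, n):
        pairs = list(itertools.combinations(range(n), 2))
        i, j = _condensed_to_pair(np.arange(len(pairs)), n)
        assert list(zip(i.tolist(), j.tolist())) == pairs


class TestDynamicK:
    @pytest.mark.parametrize("C,expected", [(2, 1), (3, 1), (10, 3), (25, 6), (100, 25)])
    def test_worked_values(self, C, expected):
        assert dynamic_k(C) == expected

    def test_always_below_class_count(self):
        for C in range(2, 60):
            assert 1 <= dynamic_k(C) < C

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            dynamic_k(1)


def points_at(centroids, spread=0.0):
    """One point per centroid (class c at centroid c)."""
    return np.asarray(centroids, float), np.arange(1, len(centroids) + 1)


class TestKNC:
    def test_identical_spaces_score_one(self, rng):
        X = rng.standard_normal((60, 5))
        labels = rng.integers(1, 7, 60)
        assert knc_preservation(X, X, labels).value == 1.0

    def test_one_changed_nearest_class_on_a_line(self):
        # 5 classes (k=1) on a line; in the embedding only B's nearest class
        # changes (A -> C); all other nearest classes are preserved -> 4/5
        high, labels = points_at([[0.0], [1.0], [2.5], [4.5], [7.0]])
        low, _ = points_at([[0.0], [1.6], [2.5], [4.5], [7.0]])
        # independent enumeration of nearest classes
        def nearest(P):
            from scipy.spatial.distance import cdist
            D = cdist(P, P)
            np.fill_diagonal(D, np.inf)
            return D.argmin(axis=1)
        nh, nl = nearest(high), nearest(low)
        assert (nh == nl).sum() == 4
        rep = knc_preservation(high, low, labels)
        assert rep.value == pytest.approx(0.8)
        assert rep.params["k"] == 1

    def test_similarity_transform_of_centroids_scores_one(self, rng, similarity):
        X = rng.standard_normal((80, 4))
        labels = rng.integers(1, 9, 80)
        assert knc_preservation(X, similarity(rng, 4)(X), labels).value == 1.0

    def test_requires_labels_classes(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValidationError):
            knc_preservation(X, X, np.ones(10, int))


class TestCentroidDistanceCorrelation:
    def test_identity_and_reflection_score_one(self, rng):
        X = rng.standard_normal((50, 4))
        labels = rng.integers(1, 6, 50)
        assert centroid_distance_correlation(X, X, labels).value == pytest.approx(1.0)
        assert centroid_distance_correlation(X, -X, labels).value == pytest.approx(1.0)

    def test_one_rank_swap_matches_manual_oracle(self):
        # 4 classes -> 6 centroid pairs; low space perturbs the geometry so
        # some distance ranks swap; compare to the manual rank correlation
        high, labels = points_at([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0], [6.0, 1.0]])
        low, _ = points_at([[0.0, 0.0], [1.1, 0.0], [2.1, 0.0], [5.0, 2.0]])
        from scipy.spatial.distance import pdist

        expected = manual_spearman(pdist(high), pdist(low))
        rep = centroid_distance_correlation(high, low, labels)
        assert rep.value == pytest.approx(expected, abs=1e-12)

    def test_too_few_classes_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        labels = np.array([1] * 5 + [2] * 5)
        with pytest.raises(ValidationError):
            centroid_distance_correlation(X, X, labels)


@pytest.mark.parametrize("metric", ["triplet", "spearman", "knc", "centroid"])
def test_invariance_under_independent_similarity_transforms(rng, similarity, metric):
    from dreval import evaluate_metric

    X = rng.standard_normal((45, 6))
    Y = rng.standard_normal((45, 2))
    labels = rng.integers(1, 6, 45)
    base = evaluate_metric(metric, X, Y, labels, seed=3)
    moved = evaluate_metric(
        metric, similarity(rng, 6)(X), similarity(rng, 2)(Y), labels, seed=3
    )
    assert moved == pytest.approx(base, abs=1e-12)
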