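import numpy as np
import pytest

from conftest import pairwise_ari, pairwise_rdc
from hci.cluster import adjusted_rand_index, estimate_k, kmeans_on_pattern, rdc
from hci.datatypes import LabelVector
from hci.synthetic import SyntheticSpec, simulate_expression


class TestKMeansOnPattern:
    def test_separable_clouds_recovered(self, two_cluster_points):
        Y, labels = two_cluster_points
        out = kmeans_on_pattern(Y, 2, seed=0)
        assert adjusted_rand_index(out.labels.labels, labels) == 1.0

    def test_k_equal_n_minus_one_merges_one_pair(self, rng):
        Y = rng.normal(size=(2, 8)) * 10
        out = kmeans_on_pattern(Y, 7, seed=0)
        sizes = np.bincount(out.labels.labels)
        assert len(sizes) == 7 and sorted(sizes) == [1] * 6 + [2]

    def test_deterministic_given_seed(self, rng):
        Y = rng.normal(size=(3, 30))
        a = kmeans_on_pattern(Y, 4, seed=7)
        b = kmeans_on_pattern(Y, 4, seed=7)
        assert np.array_equal(a.labels.labels, b.labels.labels)
        assert a.inertia == b.inertia

    @pytest.mark.parametrize("k", [1, 0, 30, 31])
    def test_k_out_of_range(self, rng, k):
        Y = rng.normal(size=(2, 30))
        with pytest.raises(ValueError, match="k must lie"):
            kmeans_on_pattern(Y, k)


class TestRDC:
    def test_collapsed_clusters_give_zero(self):
        Y = np.array([[0.0, 0.0, 5.0, 5.0]])
        assert rdc(Y, np.array([0, 0, 1, 1])) == 0.0

    def test_hand_computed_one_dimensional_example(self):
        # points {0,1} vs {10,11}: D_in = 1, D_out = (10+11+9+10)/4 = 10
        Y = np.array([[0.0, 1.0, 10.0, 11.0]])
        assert rdc(Y, np.array([0, 0, 1, 1])) == pytest.approx(0.1, abs=1e-15)

    def test_matches_allpairs_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 25))
            pts = rng.normal(size=(n, 3))
            lab = rng.integers(0, 3, size=n)
            if len(np.unique(lab)) < 2 or np.bincount(lab).max() < 2:
                continue
            assert rdc(pts.T, lab) == pytest.approx(
                pairwise_rdc(pts, lab), abs=1e-12
            )

    def test_invariant_to_rotation_and_scaling(self, rng):
        Y = rng.normal(size=(3, 20))
        lab = rng.integers(0, 2, size=20)
        lab[:2] = [0, 1]
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        base = rdc(Y, lab)
        assert rdc(Q @ Y, lab) == pytest.approx(base, abs=1e-10)
        assert rdc(7.3 * Y, lab) == pytest.approx(base, abs=1e-10)

    def test_true_labels_beat_random_permutations(self, two_cluster_points):
        Y, labels = two_cluster_points
        truth = rdc(Y, labels)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert truth < rdc(Y, rng.permutation(labels))

    def test_degenerate_partitions_error(self, rng):
        Y = rng.normal(size=(2, 6))
        with pytest.raises(ValueError, match="at least 2 clusters"):
            rdc(Y, np.zeros(6, dtype=int))
        with pytest.raises(ValueError, match="singleton"):
            rdc(Y, np.arange(6))


class TestEstimateK:
    def test_reproducible_with_fixed_seed(self, two_cluster_points):
        Y, _ = two_cluster_points
        a = estimate_k(Y, k_max=5, n_repeats=1, seed=3)
        b = estimate_k(Y, k_max=5, n_repeats=1, seed=3)
        np.testing.assert_array_equal(a.per_run_rdc, b.per_run_rdc)
        assert a.chosen_k == b.chosen_k

    def test_elbow_at_two_separated_clouds(self, two_cluster_points):
        Y, _ = two_cluster_points
        curve = estimate_k(Y, k_max=6, n_repeats=5, seed=0)
        assert curve.chosen_k == 2

    def test_three_planted_clusters_recovered(self):
        from hci.model import HCI
        from hci.preprocess import filter_zero_features, normalize_columns

        hits = 0
        for seed in range(5):
            X, _ = simulate_expression(SyntheticSpec(seed=seed))
            X = normalize_columns(filter_zero_features(X), "log1p-zscore")
            res = HCI(X).fit()
            curve = res.estimate_k(k_max=8, n_repeats=10, seed=seed)
            hits += curve.chosen_k == 3
        assert hits >= 4

    def test_chosen_k_is_smallest_plateau_k(self, rng):
        Y = rng.normal(size=(2, 40))
        curve = estimate_k(Y, k_max=6, n_repeats=3, seed=0)
        assert 2 <= curve.chosen_k <= 6
        if curve.plateau_ks:
            assert curve.chosen_k == min(curve.plateau_ks)
        assert curve.per_run_rdc.shape == (3, 5)
        assert np.all(curve.mean_rdc >= 0)

    def test_parameter_validation(self, two_cluster_points):
        Y, _ = two_cluster_points
        with pytest.raises(ValueError):
            estimate_k(Y, k_max=2)
        with pytest.raises(ValueError):
            estimate_k(Y, k_max=5, n_repeats=0)


class TestAdjustedRandIndex:
    def test_identical_partitions_up_to_relabeling(self):
        assert adjusted_rand_index(
            np.array([0, 0, 1, 1, 2]), np.array([5, 5, 9, 9, 7])
        ) == 1.0

    def test_singletons_vs_one_cluster_is_zero(self):
        assert adjusted_rand_index(np.arange(6), np.zeros(6, dtype=int)) == 0.0

    def test_matches_pair_enumeration_oracle(self, rng):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 2, 2])
        assert adjusted_rand_index(a, b) == pytest.approx(
            pairwise_ari(a, b), abs=1e-12
        )
        for _ in range(30):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 4, size=n)
            y = rng.integers(0, 4, size=n)
            assert adjusted_rand_index(x, y) == pytest.approx(
                pairwise_ari(x, y), abs=1e-12
            )

    def test_symmetry_and_label_renaming_invariance(self, rng):
        x = rng.integers(0, 3, size=25)
        y = rng.integers(0, 3, size=25)
        assert adjusted_rand_index(x, y) == pytest.approx(
            adjusted_rand_index(y, x), abs=1e-15
        )
        assert adjusted_rand_index(x, y) == pytest.approx(
            adjusted_rand_index(x, 10 - y), abs=1e-15
        )

    def test_alignment_by_sample_id(self):
        a = LabelVector(np.array([0, 0, 1, 1]), ["s1", "s2", "s3", "s4"])
        b = LabelVector(np.array([1, 1, 0, 0]), ["s3", "s4", "s1", "s2"])
        assert adjusted_rand_index(a, b) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            adjusted_rand_index(np.array([0, 1]), np.array([0, 1, 2]))
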