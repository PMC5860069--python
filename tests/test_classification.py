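import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import SQUARE_CENTRES, SQUARE_LABELS, make_blobs
from oracles import brute_force_knn, brute_force_lloyd
from dropgate import (
    ClassificationError,
    DropletTable,
    Thresholds,
    assign_centres_to_classes,
    cluster_stats,
    kmeans_classify,
    knn_classify,
    threshold_classify,
)
from dropgate.classification import lloyd


def table_of(points, labels=None):
    pts = np.asarray(points, dtype=float)
    return DropletTable(pts[:, 0], pts[:, 1], labels)


class TestThresholdClassify:
    TH = Thresholds(6789.0, 3000.0)

    @pytest.mark.parametrize(
        "point,expected",
        [
            ((7000.0, 3500.0), "PP"),
            ((7000.0, 2000.0), "PN"),
            ((5000.0, 3500.0), "NP"),
            ((5000.0, 2000.0), "NN"),
            ((6789.0, 3000.0), "PP"),  # boundary droplet counts as positive
        ],
    )
    def test_gating_rule(self, point, expected):
        t = threshold_classify(table_of([point]), self.TH)
        assert t.labels.tolist() == [expected]

    def test_never_produces_rain(self, rng):
        t = table_of(rng.uniform(0, 10000, size=(200, 2)))
        out = threshold_classify(t, self.TH)
        assert "Rain" not in out.labels
        assert "Unclassified" not in out.labels

    @given(lo=st.floats(0, 10000), hi=st.floats(0, 10000))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_monotone_in_ch1_threshold(self, lo, hi):
        lo, hi = sorted((lo, hi))
        amps = np.linspace(0, 10000, 101)
        t = table_of(np.column_stack([amps, amps]))
        pos_low = np.isin(threshold_classify(t, Thresholds(lo, 0.0)).labels, ["PN", "PP"])
        pos_high = np.isin(threshold_classify(t, Thresholds(hi, 0.0)).labels, ["PN", "PP"])
        # raising the Channel 1 threshold never converts a negative to positive
        assert not (pos_high & ~pos_low).any()

    def test_amplitudes_unchanged(self, blob_table):
        out = threshold_classify(blob_table, self.TH)
        assert len(out) == len(blob_table)
        assert out.ch1.tolist() == blob_table.ch1.tolist()
        assert out.ch2.tolist() == blob_table.ch2.tolist()


class TestAssignCentres:
    CENTRES = [(1000, 1000), (1000, 8000), (9000, 1000), (9000, 8000)]
    EXPECTED = ["NN", "NP", "PN", "PP"]

    def test_square_geometry(self):
        mapping = assign_centres_to_classes(self.CENTRES)
        assert [mapping[i] for i in range(4)] == self.EXPECTED

    def test_permutation_invariant(self):
        for perm in itertools.permutations(range(4)):
            centres = [self.CENTRES[i] for i in perm]
            mapping = assign_centres_to_classes(centres)
            assert [mapping[j] for j in range(4)] == [self.EXPECTED[i] for i in perm]

    def test_duplicate_centres_error(self):
        with pytest.raises(ClassificationError):
            assign_centres_to_classes([(0, 0), (0, 0), (1, 1), (2, 2)])

    def test_leaning_geometry(self):
        # PN has larger ch1, NP larger ch2, even when clusters lean
        mapping = assign_centres_to_classes([(2000, 1500), (2500, 7500), (9000, 1800), (9500, 8000)])
        assert [mapping[i] for i in range(4)] == ["NN", "NP", "PN", "PP"]


class TestKmeans:
    def test_fixed_point_on_separated_blobs(self, blob_table):
        labelled, stats = kmeans_classify(blob_table, initial_centres=SQUARE_CENTRES)
        assert labelled.labels.tolist() == list(np.repeat(SQUARE_LABELS, 50))
        assert {s.label: s.count for s in stats} == {l: 50 for l in SQUARE_LABELS}

    def test_matches_brute_force_lloyd(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 500))
            X = rng.uniform(0, 10000, size=(n, 2))
            centres = rng.uniform(0, 10000, size=(4, 2))
            t = table_of(X)
            try:
                expected_assign, expected_centres = brute_force_lloyd(X, centres)
            except ValueError:
                with pytest.raises(ClassificationError):
                    kmeans_classify(t, initial_centres=centres)
                continue
            labelled, _ = kmeans_classify(t, initial_centres=centres)
            mapping = assign_centres_to_classes(expected_centres)
            expected_labels = [mapping[j] for j in expected_assign]
            assert labelled.labels.tolist() == expected_labels

    def test_wcss_non_increasing(self, rng):
        for _ in range(5):
            X = rng.uniform(0, 10000, size=(300, 2))
            result = lloyd(X, rng.uniform(2000, 8000, size=(4, 2)))
            assert all(b <= a + 1e-9 for a, b in zip(result.wcss, result.wcss[1:]))

    def test_too_few_droplets(self):
        with pytest.raises(ClassificationError):
            kmeans_classify(table_of([(0, 0), (1, 1), (2, 2)]))

    def test_degenerate_identical_amplitudes(self):
        with pytest.raises(ClassificationError):
            kmeans_classify(table_of([(5, 5)] * 10))

    def test_empty_cluster_names_initial_centre(self, blob_table):
        centres = np.array([[1000, 1000], [1000, 8000], [9000, 1000], [1e9, 1e9]])
        with pytest.raises(ClassificationError, match="empty cluster"):
            kmeans_classify(blob_table, initial_centres=centres)

    def test_standardize_recovers_same_blobs(self, blob_table):
        labelled, _ = kmeans_classify(
            blob_table, initial_centres=SQUARE_CENTRES, standardize=True
        )
        assert labelled.labels.tolist() == list(np.repeat(SQUARE_LABELS, 50))


class TestKnn:
    def train_table(self, rng):
        return make_blobs(rng, SQUARE_CENTRES, n_per=25, sd=200.0, labels=SQUARE_LABELS)

    def test_coincident_droplet_k1(self, rng):
        train = self.train_table(rng)
        query = table_of([[train.ch1[70], train.ch2[70]]])
        out = knn_classify(query, train, k=1)
        assert out.labels.tolist() == [train.labels[70]]

    def test_split_vote_unclassified(self):
        train = table_of([(0, 0), (10, 10)], labels=["NN", "PP"])
        out = knn_classify(table_of([(5, 5)]), train, k=2, min_vote_fraction=0.6)
        assert out.labels.tolist() == ["Unclassified"]

    def test_matches_brute_force(self, rng):
        train = self.train_table(rng)
        for k in (1, 3, 7):
            X = rng.uniform(0, 10000, size=(400, 2))
            expected = brute_force_knn(X, train.amplitudes, train.labels, k, 0.51)
            out = knn_classify(table_of(X), train, k=k, min_vote_fraction=0.51)
            assert out.labels.tolist() == expected.tolist()

    def test_invalid_training_labels(self):
        train = table_of([(0, 0)], labels=["Rain"])
        with pytest.raises(ClassificationError, match="training labels"):
            knn_classify(table_of([(1, 1)]), train)

    def test_k_bounds(self, rng):
        train = self.train_table(rng)
        with pytest.raises(ClassificationError):
            knn_classify(table_of([(1, 1)]), train, k=len(train) + 1)


class TestClusterStats:
    def test_hand_computed_covariance(self):
        t = table_of([(0, 0), (2, 2)], labels=["PP", "PP"])
        (s,) = cluster_stats(t)
        assert s.label == "PP"
        assert s.count == 2
        np.testing.assert_allclose(s.mean, [1.0, 1.0])
        np.testing.assert_allclose(s.covariance, [[2.0, 2.0], [2.0, 2.0]])

    def test_singleton_flagged_zero_covariance(self):
        t = table_of([(3, 4)], labels=["NN"])
        (s,) = cluster_stats(t)
        assert s.singleton
        np.testing.assert_array_equal(s.covariance, np.zeros((2, 2)))
        np.testing.assert_allclose(s.mean, [3.0, 4.0])

    def test_absent_class_omitted_and_rain_excluded(self):
        t = table_of([(0, 0), (1, 1), (5, 5)], labels=["NN", "NN", "Rain"])
        stats = cluster_stats(t)
        assert [s.label for s in stats] == ["NN"]
        assert stats[0].count == 2
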