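"""Confusion matrices, accuracy, sensitivity, ROC/AUC, repetition stats."""

import numpy as np
import pytest

import oracles
import weedvision as wv

# published test-set confusion matrices for the four data categories
ANN_BA_MATRICES = {
    "left": [[89, 6, 2], [12, 67, 6], [2, 1, 56]],
    "right": [[86, 3, 1], [6, 73, 10], [2, 4, 46]],
    "arithmetic": [[91, 5, 1], [6, 69, 2], [1, 3, 48]],
    "geometric": [[91, 6, 0], [7, 67, 3], [3, 2, 47]],
}
KNN_MATRICES = {
    "left": [[83, 8, 6], [10, 65, 10], [0, 0, 59]],
    "right": [[65, 19, 6], [17, 60, 12], [0, 0, 52]],
    "arithmetic": [[83, 8, 6], [11, 62, 4], [3, 0, 49]],
    "geometric": [[78, 15, 4], [12, 60, 5], [0, 0, 52]],
}


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = [1, 2, 3, 1, 2, 3]
        cm = wv.confusion(y, y)
        assert np.array_equal(cm, np.diag([2, 2, 2]))

    def test_empty_input_zero_matrix(self):
        assert np.array_equal(wv.confusion([], []), np.zeros((3, 3), dtype=int))

    def test_hand_counted_case(self):
        cm = wv.confusion([1, 1, 2, 3], [1, 2, 2, 3])
        assert cm[0, 0] == 1 and cm[0, 1] == 1
        assert cm[1, 1] == 1 and cm[2, 2] == 1
        assert cm.sum() == 4

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError):
            wv.confusion([1, 4], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wv.confusion([1, 2], [1])


class TestOverallAccuracy:
    def test_right_channel_ann_ba(self):
        assert wv.overall_accuracy(ANN_BA_MATRICES["right"]) == 88.74

    @pytest.mark.parametrize("cat,expected", [
        ("right", 76.62), ("arithmetic", 85.84), ("geometric", 84.07),
        ("left", 85.89),
    ])
    def test_knn_matrices(self, cat, expected):
        assert wv.overall_accuracy(KNN_MATRICES[cat]) == expected

    def test_diagonal_matrix_is_100(self):
        assert wv.overall_accuracy(np.diag([5, 7, 3])) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wv.overall_accuracy(np.zeros((3, 3)))

    def test_invariant_under_class_permutation(self, rng):
        cm = rng.integers(0, 50, size=(3, 3))
        cm[0, 0] += 1  # nonempty
        perm = rng.permutation(3)
        permuted = cm[np.ix_(perm, perm)]
        assert wv.overall_accuracy(cm) == wv.overall_accuracy(permuted)


class TestClassSensitivity:
    def test_left_channel_rice_row(self):
        # rice row (89, 6, 2): 89 of 97 correct
        assert wv.class_sensitivity(ANN_BA_MATRICES["left"], 1) == \
            pytest.approx(89 / 97)

    def test_diagonal_matrix_all_ones(self):
        cm = np.diag([4, 4, 4])
        for c in (1, 2, 3):
            assert wv.class_sensitivity(cm, c) == 1.0

    def test_zero_correct(self):
        cm = [[0, 5, 5], [0, 1, 0], [0, 0, 1]]
        assert wv.class_sensitivity(cm, 1) == 0.0

    def test_empty_row_flagged(self):
        cm = [[0, 0, 0], [0, 1, 0], [0, 0, 1]]
        with pytest.raises(ValueError):
            wv.class_sensitivity(cm, 1)


class TestROC:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        actual = [1, 1, 2, 3]
        assert wv.roc_curve(scores, actual, 1).auc == pytest.approx(1.0)

    def test_inverted_scores(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        actual = [1, 1, 2, 3]
        assert wv.roc_curve(scores, actual, 1).auc == pytest.approx(0.0)

    def test_hand_case_three_quarters(self):
        # positives rank 1st and 3rd: 3 of 4 pos-neg pairs ordered correctly
        scores = [0.9, 0.8, 0.3, 0.1]
        actual = [1, 2, 1, 3]
        assert wv.roc_curve(scores, actual, 1).auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.uniform(size=30)
        actual = rng.integers(1, 4, size=30)
        curve = wv.roc_curve(scores, actual, 2)
        assert curve.auc == pytest.approx(
            oracles.auc_by_pairs(scores, actual == 2), rel=1e-9)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all((curve.tpr >= 0) & (curve.tpr <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            wv.roc_curve([0.5, 0.6], [1, 1], 1)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(99)
        scores = rng.uniform(size=60)
        aucs = []
        for _ in range(200):
            labels = rng.permutation([1] * 20 + [2] * 20 + [3] * 20)
            aucs.append(wv.roc_curve(scores, labels, 1).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestRepetitionStats:
    def test_constant_list_zero_std(self):
        mean, std = wv.repetition_stats([0.9, 0.9, 0.9])
        assert mean == pytest.approx(0.9) and std == 0.0

    def test_two_point_formula(self):
        mean, std = wv.repetition_stats([0.8, 1.0])
        assert mean == pytest.approx(0.9)
        assert std == pytest.approx(np.sqrt(0.02))

    def test_matches_streaming_oracle(self, rng):
        accs = rng.uniform(0.7, 1.0, size=1000)
        mean, std = wv.repetition_stats(accs)
        # Welford's streaming algorithm as an independent route
        m, m2, n = 0.0, 0.0, 0
        for a in accs:
            n += 1
            d = a - m
            m += d / n
            m2 += d * (a - m)
        assert mean == pytest.approx(m, rel=1e-12)
        assert std == pytest.approx(np.sqrt(m2 / (n - 1)), rel=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            wv.repetition_stats([0.9])
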