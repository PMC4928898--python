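"""Closed-form least-squares LDA: training, decision rule, metrics."""

import numpy as np
import pytest

import bisqc as b
from bisqc.lslda import (LabeledDataset, LinearClassifier, classification_error,
                         confusion_matrix, mean_squared_error, predict,
                         train_lslda)


def _random_dataset(rng, p=5, c=3, l=60):
    x = rng.standard_normal((p, l))
    y = rng.integers(1, c + 1, size=l)
    for cls in range(1, c + 1):  # ensure every class occupied
        y[cls - 1] = cls
        x[:, y == cls] += cls  # displace class means
    return LabeledDataset(x, y, tuple(f"c{i}" for i in range(1, c + 1)))


class TestTrain:
    def test_symmetric_two_sample_boundary_at_zero(self):
        data = LabeledDataset(np.array([[-1.0, 1.0]]), np.array([1, 2]),
                              ("a", "b"))
        clf = train_lslda(data)
        assert clf.predict(np.array([[-1.0, 1.0]])).tolist() == [1, 2]
        # boundary: outputs equal at x = 0
        y = clf.decision(np.array([[0.0]]))
        assert y[0, 0] == pytest.approx(y[1, 0])
        assert predict(clf, np.array([-2.0])) == 1

    def test_matches_iterative_least_squares_oracle(self, rng):
        from scipy.sparse.linalg import lsqr

        data = _random_dataset(rng)
        clf = train_lslda(data)
        q = np.vstack([np.ones(data.n_samples), data.patterns])
        t = np.zeros((data.n_classes, data.n_samples))
        t[data.labels - 1, np.arange(data.n_samples)] = 1
        v_oracle = np.vstack([
            lsqr(q.T, t[c], atol=1e-14, btol=1e-14, iter_lim=10000)[0]
            for c in range(data.n_classes)
        ])
        assert np.allclose(clf.weights, v_oracle, atol=1e-8)

    def test_closed_form_attains_minimum_mse(self, rng):
        for _ in range(10):
            data = _random_dataset(rng, p=4, c=3, l=40)
            clf = train_lslda(data)
            base = mean_squared_error(clf, data)
            for _ in range(20):
                w = clf.weights + 1e-3 * rng.standard_normal(clf.weights.shape)
                pert = LinearClassifier(w, clf.feature_mask, clf.class_names)
                assert base <= mean_squared_error(pert, data) + 1e-15

    def test_affine_shift_absorbed_by_bias(self, rng):
        data = _random_dataset(rng)
        shifted = LabeledDataset(data.patterns + np.array([[5.0], [0], [0], [0], [0]]),
                                 data.labels, data.class_names)
        c1, c2 = train_lslda(data), train_lslda(shifted)
        y1 = c1.decision(data.patterns)
        y2 = c2.decision(shifted.patterns)
        assert np.allclose(y1, y2, atol=1e-9)
        # only bias and the shifted feature's weight may differ
        assert np.allclose(c1.weights[:, 2:], c2.weights[:, 2:], atol=1e-9)

    def test_sample_order_invariance(self, rng):
        data = _random_dataset(rng)
        perm = rng.permutation(data.n_samples)
        shuffled = LabeledDataset(data.patterns[:, perm], data.labels[perm],
                                  data.class_names)
        assert np.allclose(train_lslda(data).weights,
                           train_lslda(shuffled).weights, atol=1e-9)

    def test_empty_class_rejected(self):
        data = LabeledDataset(np.array([[0.0, 1.0]]), np.array([1, 1]),
                              ("a", "b"))
        with pytest.raises(ValueError, match="empty class"):
            train_lslda(data)

    def test_feature_mask_restricts_inputs(self, rng):
        data = _random_dataset(rng)
        clf = train_lslda(data, feature_mask=(0, 3))
        assert clf.weights.shape == (3, 3)
        assert clf.predict(data.patterns).shape == (data.n_samples,)


class TestDecision:
    def test_argmax_and_tie_break(self):
        clf = LinearClassifier(np.array([[0.0, 1.0], [0.0, -1.0]]), (0,),
                               ("a", "b"))
        assert predict(clf, np.array([0.5])) == 1
        assert predict(clf, np.array([0.0])) == 1  # tie -> lowest index
        assert predict(clf, np.array([-0.5])) == 2

    def test_dimension_mismatch_rejected(self):
        clf = LinearClassifier(np.array([[0.0, 1.0], [0.0, -1.0]]), (0,),
                               ("a", "b"))
        with pytest.raises(ValueError):
            predict(clf, np.array([1.0, 2.0]))


class TestMetrics:
    def test_error_percentage_exact_fractions(self):
        truth = np.ones(601, dtype=int)
        pred = truth.copy()
        assert classification_error(pred, truth) == 0.0
        pred[0] = 2
        assert classification_error(pred, truth) == pytest.approx(100 / 601)
        assert round(classification_error(pred, truth), 2) == 0.17
        pred[:34] = 2
        assert classification_error(pred, truth) == pytest.approx(3400 / 601)
        assert round(classification_error(pred, truth), 1) == 5.7

    def test_confusion_diagonal_for_perfect_predictions(self):
        y = np.array([1, 2, 3, 3, 2, 1])
        assert np.array_equal(confusion_matrix(y, y, 3),
                              np.diag([2, 2, 2]))

    def test_confusion_fully_confused_pair(self):
        # 12 samples of class 7 all predicted as class 6
        truth = np.full(12, 7)
        pred = np.full(12, 6)
        cm = confusion_matrix(pred, truth, 7)
        assert cm[6, 5] == 12 and cm[6, 6] == 0

    def test_confusion_matches_counting_oracle(self, rng):
        truth = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        cm = confusion_matrix(pred, truth, 4)
        for i in range(4):
            for j in range(4):
                assert cm[i, j] == np.sum((truth == i + 1) & (pred == j + 1))
        assert np.array_equal(cm.sum(axis=1), np.bincount(truth, minlength=5)[1:])

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.array([1, 5]), np.array([1, 2]), 4)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        clf = train_lslda(_random_dataset(rng), feature_mask=(1, 2, 4))
        path = tmp_path / "clf.json"
        clf.save(path)
        loaded = LinearClassifier.load(path)
        assert np.array_equal(loaded.weights, clf.weights)
        assert loaded.feature_mask == clf.feature_mask
        assert loaded.class_names == clf.class_names
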