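"""Multi-class least-squares linear discriminant analysis.

Patterns are collected columnwise in a P x L matrix.  With Q = [1; P]
(a row of ones stacked on the pattern matrix) and T the C x L one-hot
target matrix, the weight matrix minimising the mean squared error
``MSE = ||V Q - T||^2 / L`` has the closed form

    V = T Q' (Q Q')^{-1}

implemented here via a linear solve (pseudo-inverse fallback when the
Gram matrix is rank-deficient).  Classification is the argmax over the C
linear outputs y = V [1; x], ties broken toward the lowest class index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledDataset",
    "LinearClassifier",
    "train_lslda",
    "predict",
    "classification_error",
    "confusion_matrix",
    "mean_squared_error",
]

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class LabeledDataset:
    """Feature patterns (P features x L samples) with integer labels 1..C."""

    patterns: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        patterns = np.asarray(self.patterns, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if patterns.ndim != 2:
            raise ValueError("patterns must be a 2-d (P x L) matrix")
        if labels.shape != (patterns.shape[1],):
            raise ValueError("one label per pattern column required")
        if not np.all(np.isfinite(patterns)):
            raise ValueError("non-finite feature values in patterns")
        c = len(self.class_names)
        if labels.size and (labels.min() < 1 or labels.max() > c):
            raise ValueError(f"labels must lie in 1..{c}")
        object.__setattr__(self, "patterns", patterns)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_features(self) -> int:
        return int(self.patterns.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.patterns.shape[1])

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, columns: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.patterns[:, columns], self.labels[columns],
                              self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    t = np.zeros((n_classes, labels.size))
    t[labels - 1, np.arange(labels.size)] = 1.0
    return t


@dataclass(frozen=True)
class LinearClassifier:
    """LS-LDA weight matrix with the feature mask it consumes.

    ``weights`` is C x (1 + m): bias first, then one column per selected
    feature.  ``feature_mask`` holds the 0-based indices (into the full
    feature space) this classifier consumes, in order.
    """

    weights: np.ndarray
    feature_mask: tuple[int, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite classifier weights")
        if w.shape != (len(self.class_names), 1 + len(self.feature_mask)):
            raise ValueError("weights shape inconsistent with mask/classes")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "feature_mask", tuple(int(i) for i in self.feature_mask))
        object.__setattr__(self, "class_names", tuple(self.class_names))

    def decision(self, patterns: np.ndarray) -> np.ndarray:
        """C x L matrix of discriminant outputs for full-space patterns."""
        patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
        x = patterns[list(self.feature_mask), :]
        q = np.vstack([np.ones((1, x.shape[1])), x])
        return self.weights @ q

    def predict(self, patterns: np.ndarray) -> np.ndarray:
        """Predicted labels (1..C); argmax ties go to the lowest class index."""
        return np.argmax(self.decision(patterns), axis=0) + 1

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "bisqc-linear-classifier",
            "version": _SERIAL_VERSION,
            "class_names": list(self.class_names),
            "feature_mask": list(self.feature_mask),
            "weights": self.weights.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LinearClassifier":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "bisqc-linear-classifier":
            raise ValueError(f"{path}: not a classifier file")
        return cls(np.array(doc["weights"]), tuple(doc["feature_mask"]),
                   tuple(doc["class_names"]))


def train_lslda(data: LabeledDataset,
                feature_mask: tuple[int, ...] | None = None) -> LinearClassifier:
    """Closed-form LS-LDA training.

    Parameters
    ----------
    data : LabeledDataset
        Training set; every class 1..C must have at least one sample.
    feature_mask : tuple of int, optional
        0-based indices of the features to use; defaults to all.
    """
    counts = data.class_counts()
    if np.any(counts == 0):
        missing = [data.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"empty class(es) in training data: {missing}")
    if feature_mask is None:
        feature_mask = tuple(range(data.n_features))
    p = data.patterns[list(feature_mask), :]
    l = p.shape[1]
    q = np.vstack([np.ones((1, l)), p])
    t = _one_hot(data.labels, data.n_classes)
    gram = q @ q.T
    rhs = t @ q.T
    # V = rhs @ gram^{-1}  <=>  gram' V' = rhs'  (gram symmetric)
    try:
        v = np.linalg.solve(gram, rhs.T).T
        if not np.all(np.isfinite(v)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        warnings.warn("singular Gram matrix: falling back to pseudo-inverse",
                      stacklevel=2)
        v = rhs @ np.linalg.pinv(gram)
    return LinearClassifier(v, feature_mask, data.class_names)


def predict(clf: LinearClassifier, x: np.ndarray) -> int:
    """Label of a single already-masked feature vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(clf.feature_mask):
        raise ValueError(
            f"expected {len(clf.feature_mask)} features, got {x.size}")
    y = clf.weights @ np.concatenate([[1.0], x])
    return int(np.argmax(y)) + 1


def mean_squared_error(clf: LinearClassifier, data: LabeledDataset) -> float:
    """The trained objective ||V Q - T||^2 / L on a dataset."""
    y = clf.decision(data.patterns)
    t = _one_hot(data.labels, data.n_classes)
    return float(np.sum((y - t) ** 2) / data.n_samples)


def classification_error(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of misclassified samples."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be nonempty, equal-length")
    return 100.0 * float(np.count_nonzero(predictions != truth)) / predictions.size


def confusion_matrix(predictions: np.ndarray, truth: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """Count matrix: entry (i, j) = samples of true class i+1 predicted j+1."""
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError("length mismatch")
    for arr, name in ((predictions, "predictions"), (truth, "truth")):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} contain labels outside 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (truth - 1, predictions - 1), 1)
    return cm
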