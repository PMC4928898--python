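"""Fisher-score feature ranking and one-feature threshold sub-classifiers.

For two classes the Fisher score of a feature is

    F = ((mu_ci - mu)^2 + (mu_cj - mu)^2) / sigma^2

with mu, sigma the mean and (population) standard deviation of the pooled
values and mu_ci, mu_cj the class means.  The highest-scoring feature
feeds a binary one-feature LS-LDA whose decision boundary reduces to a
scalar threshold x* = (v20 - v10) / (v11 - v21); the deployed threshold
is the average of the per-fold boundaries of a k-fold design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evo import stratified_folds
from .lslda import LabeledDataset, train_lslda

__all__ = ["ThresholdClassifier", "fisher_score", "select_best_feature",
           "train_threshold", "classify_by_threshold"]


def fisher_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Fisher separability score of one feature for a two-class sample.

    Raises
    ------
    ValueError
        If a class is empty or the pooled standard deviation is zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    mu = values.mean()
    sigma = values.std()  # population (1/N) convention
    if sigma == 0:
        raise ValueError("zero pooled standard deviation")
    mi = values[labels == classes[0]].mean()
    mj = values[labels == classes[1]].mean()
    return float(((mi - mu) ** 2 + (mj - mu) ** 2) / sigma**2)


def select_best_feature(data: LabeledDataset) -> int:
    """0-based index of the Fisher-score argmax feature; ties to lowest index.

    Features whose pooled standard deviation is zero are skipped (they
    carry no separation).
    """
    classes = np.unique(data.labels)
    if classes.size != 2:
        raise ValueError("dataset must contain exactly two classes")
    best_idx, best_score = -1, -np.inf
    for k in range(data.n_features):
        col = data.patterns[k]
        if col.std() == 0:
            continue
        s = fisher_score(col, data.labels)
        if s > best_score:
            best_idx, best_score = k, s
    if best_idx < 0:
        raise ValueError("all features are constant")
    return best_idx


@dataclass(frozen=True)
class ThresholdClassifier:
    """Scalar decision threshold on one feature for a two-class problem.

    ``class_below`` / ``class_above`` are the labels assigned on either
    side; a value exactly at the threshold goes to ``class_below``.
    ``feature_index`` is 0-based into the full feature space.
    """

    feature_index: int
    threshold: float
    class_below: int
    class_above: int
    fold_thresholds: tuple[float, ...]

    def summary(self) -> str:
        return (f"one-feature threshold on f{self.feature_index + 1}: "
                f"x > {self.threshold:.6g} -> class {self.class_above}, "
                f"else class {self.class_below} "
                f"(mean of {len(self.fold_thresholds)} fold thresholds)")


def _fold_boundary(values: np.ndarray, labels: np.ndarray) -> float:
    """Boundary of a binary one-feature LS-LDA: the output-equality point."""
    classes = np.unique(labels)
    relab = np.where(labels == classes[0], 1, 2)
    data = LabeledDataset(values[None, :], relab, ("c1", "c2"))
    v = train_lslda(data).weights
    denom = v[0, 1] - v[1, 1]
    if denom == 0:
        raise ValueError("parallel discriminants: no threshold exists")
    return float((v[1, 0] - v[0, 0]) / denom)


def train_threshold(values: np.ndarray, labels: np.ndarray, folds: int,
                    rng: np.random.Generator, feature_index: int = 0,
                    ) -> ThresholdClassifier:
    """Average the per-fold one-feature LS-LDA boundaries into a threshold.

    Each fold's training half (the other k-1 folds) yields one boundary;
    the deployed threshold is their mean.  Orientation is set from which
    class mean lies above the threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    assignment = stratified_folds(labels, folds, rng)
    bounds = []
    for f in range(folds):
        train = assignment != f
        bounds.append(_fold_boundary(values[train], labels[train]))
    threshold = float(np.mean(bounds))
    mean_a = values[labels == classes[0]].mean()
    mean_b = values[labels == classes[1]].mean()
    if mean_a > mean_b:
        above, below = int(classes[0]), int(classes[1])
    else:
        above, below = int(classes[1]), int(classes[0])
    return ThresholdClassifier(feature_index, threshold, below, above,
                               tuple(bounds))


def classify_by_threshold(x: float, clf: ThresholdClassifier) -> int:
    """Side-of-threshold decision; x exactly at the threshold -> class_below."""
    return clf.class_above if x > clf.threshold else clf.class_below
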