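"""End-to-end detection/classification pipelines.

Two schemes are assembled from the lower-level modules:

* **all-at-once** — one LS-LDA over the seven full-resolution classes,
  on a feature subset chosen by the evolutionary wrapper;
* **divide and conquer** — step 1 classifies five merged classes (B+C
  and E+F pooled) with an EA-selected LS-LDA; step 2 splits each pooled
  pair with a one-feature threshold classifier, the feature picked by
  Fisher score on the design samples of the pair.

Both are exposed statsmodels-style: a Model object holds the design
data and settings, ``fit()`` returns a Results object with the trained
classifier(s), the selection history, ``predict`` and ``evaluate``.
The design/test split is stratified per class (60/40 by default) and
test samples are never touched during fitting or selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .classes import MERGED_OF, ErrorClass, MergedClass, merge_label
from .cole import ColeModel
from .evo import EAConfig, EAResult, run_ea
from .features import N_FEATURES, extract_features
from .fisher import (ThresholdClassifier, classify_by_threshold,
                     select_best_feature, train_threshold)
from .immittance import components
from .lslda import (LabeledDataset, LinearClassifier, classification_error,
                    confusion_matrix, train_lslda)
from .synth import SpectraCollection

__all__ = [
    "ERROR_CLASS_NAMES",
    "MERGED_CLASS_NAMES",
    "build_feature_dataset",
    "split_indices",
    "split_dataset",
    "AllAtOnceModel",
    "AllAtOnceResults",
    "DivideConquerModel",
    "DivideConquerResults",
    "EvaluationReport",
    "train_all_at_once",
    "train_divide_conquer",
    "predict_divide_conquer",
    "evaluate",
]

ERROR_CLASS_NAMES = tuple(c.name for c in ErrorClass)
MERGED_CLASS_NAMES = tuple(c.name for c in MergedClass)


def build_feature_dataset(collection: SpectraCollection) -> LabeledDataset:
    """Fit the Cole model to every spectrum and extract the 31 features.

    The fitted characteristic frequency of each measurement anchors its
    own band partition, so features are comparable across applications.
    Per-sample empty-band warnings (routine when a fitted characteristic
    frequency sits near the grid edge) are silenced here; the zero
    feature values still record the fact.
    """
    import warnings

    columns = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="empty band")
        for sample in collection.samples:
            res = ColeModel(sample.spectrum).fit()
            measured = components(sample.spectrum)
            fitted = components(res.predict())
            fv = extract_features(measured, fitted, res.params.omega_c)
            columns.append(fv.values)
    patterns = np.column_stack(columns) if columns else np.empty((N_FEATURES, 0))
    return LabeledDataset(patterns, collection.labels, ERROR_CLASS_NAMES)


def split_indices(labels: np.ndarray, design_fraction: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified design/test index split.

    Per class, ``round(design_fraction * n_class)`` samples are drawn
    uniformly without replacement into the design set; the remainder
    form the test set.
    """
    labels = np.asarray(labels)
    design, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            raise ValueError(f"empty class {c}")
        n_design = int(round(design_fraction * idx.size))
        chosen = rng.choice(idx, size=n_design, replace=False)
        design.append(np.sort(chosen))
        test.append(np.setdiff1d(idx, chosen))
    return np.concatenate(design), np.concatenate(test)


def split_dataset(data: LabeledDataset, design_fraction: float = 0.60,
                  rng_seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified 60/40 design/test split of a feature dataset."""
    rng = np.random.default_rng(rng_seed)
    d_idx, t_idx = split_indices(data.labels, design_fraction, rng)
    return data.subset(d_idx), data.subset(t_idx)


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set performance: overall error and 7-class confusion matrix.

    For the divide-and-conquer scheme the per-step figures are filled:
    step-1 error over the five merged classes, and the two sub-classifier
    errors over the true B/C and E/F test samples respectively.
    """

    error_pct: float
    confusion: np.ndarray
    class_names: tuple[str, ...]
    step1_error_pct: float | None = None
    step1_confusion: np.ndarray | None = None
    bc_error_pct: float | None = None
    bc_confusion: np.ndarray | None = None
    ef_error_pct: float | None = None
    ef_confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "error_pct": self.error_pct,
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
        }
        for key in ("step1_error_pct", "bc_error_pct", "ef_error_pct"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        for key in ("step1_confusion", "bc_confusion", "ef_confusion"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value.tolist()
        return out

    def summary(self) -> str:
        lines = [f"overall test error: {self.error_pct:.2f}%", ""]
        lines += _format_confusion(self.confusion, self.class_names)
        if self.step1_error_pct is not None:
            lines += ["", f"step 1 (merged classes) error: {self.step1_error_pct:.2f}%"]
        if self.bc_error_pct is not None:
            lines.append(f"step 2 B/C error: {self.bc_error_pct:.2f}%")
        if self.ef_error_pct is not None:
            lines.append(f"step 2 E/F error: {self.ef_error_pct:.2f}%")
        return "\n".join(lines)


def _format_confusion(cm: np.ndarray, names: tuple[str, ...]) -> list[str]:
    width = max(len(n) for n in names) + 2
    header = " " * width + "".join(f"{n:>{width}}" for n in names)
    rows = [header]
    for i, name in enumerate(names):
        rows.append(f"{name:>{width}}" + "".join(f"{v:>{width}d}" for v in cm[i]))
    return rows


def evaluate(predictions: np.ndarray, truth: np.ndarray,
             class_names: tuple[str, ...]) -> EvaluationReport:
    """Overall error and confusion matrix of full-resolution predictions."""
    return EvaluationReport(
        error_pct=classification_error(predictions, truth),
        confusion=confusion_matrix(predictions, truth, len(class_names)),
        class_names=class_names,
    )


class AllAtOnceModel:
    """Seven-class LS-LDA with EA wrapper feature selection.

    Parameters
    ----------
    design : LabeledDataset
        Design set with full-resolution labels 1..7; never include test
        samples here.
    n_feat : int
        Feature budget for the evolutionary selection (default 7).
    ea_config : EAConfig, optional
        Full EA settings; ``n_feat`` and ``rng_seed`` arguments override
        the corresponding config fields.
    """

    scheme = "all-at-once"

    def __init__(self, design: LabeledDataset, n_feat: int = 7,
                 ea_config: EAConfig | None = None, rng_seed: int = 0):
        if design.n_classes != len(ErrorClass):
            raise ValueError("design set must carry the 7 full-resolution classes")
        self.design = design
        self.ea_config = replace(ea_config or EAConfig(),
                                 n_feat=n_feat, rng_seed=rng_seed)

    def fit(self) -> "AllAtOnceResults":
        ea = run_ea(self.design, self.ea_config)
        mask = tuple(int(i) for i in np.flatnonzero(ea.best_mask))
        clf = train_lslda(self.design, feature_mask=mask)
        return AllAtOnceResults(self, clf, ea)


@dataclass
class AllAtOnceResults:
    model: AllAtOnceModel
    classifier: LinearClassifier
    ea: EAResult

    @property
    def selected_features(self) -> tuple[int, ...]:
        """1-based indices (f1..f31) of the EA-selected features."""
        return self.ea.selected_features

    def predict(self, patterns: np.ndarray) -> np.ndarray:
        """Full-resolution labels 1..7 for full-space feature patterns."""
        return self.classifier.predict(patterns)

    def evaluate(self, test: LabeledDataset) -> EvaluationReport:
        return evaluate(self.predict(test.patterns), test.labels,
                        ERROR_CLASS_NAMES)

    def summary(self) -> str:
        names = ", ".join(f"f{i}" for i in self.selected_features)
        return "\n".join([
            "All-at-once scheme (7 classes, one LS-LDA)",
            "==========================================",
            f"  design samples   {self.model.design.n_samples}",
            f"  feature budget   {self.model.ea_config.n_feat}",
            f"  selected         {names}",
            f"  CV error (EA)    {self.ea.best_fitness:.2f}%",
        ])


class DivideConquerModel:
    """Two-step scheme: merged 5-class LS-LDA, then one-feature splits.

    Step 1 trains on labels merged per the B+C / E+F pooling; step 2
    builds one-feature threshold classifiers from the design samples of
    each pooled pair, the feature chosen by Fisher score.
    """

    scheme = "divide-conquer"

    def __init__(self, design: LabeledDataset, n_feat: int = 7,
                 ea_config: EAConfig | None = None, rng_seed: int = 0):
        if design.n_classes != len(ErrorClass):
            raise ValueError("design set must carry the 7 full-resolution classes")
        self.design = design
        self.ea_config = replace(ea_config or EAConfig(),
                                 n_feat=n_feat, rng_seed=rng_seed)

    def _merged_design(self) -> LabeledDataset:
        merged = np.array([int(merge_label(c)) for c in self.design.labels])
        return LabeledDataset(self.design.patterns, merged, MERGED_CLASS_NAMES)

    def _sub_threshold(self, pair: tuple[ErrorClass, ErrorClass],
                       rng: np.random.Generator) -> ThresholdClassifier:
        sel = np.isin(self.design.labels, [int(pair[0]), int(pair[1])])
        sub = self.design.subset(np.flatnonzero(sel))
        feat = select_best_feature(sub)
        clf = train_threshold(sub.patterns[feat], sub.labels,
                              folds=self.ea_config.cv_folds, rng=rng,
                              feature_index=feat)
        return clf

    def fit(self) -> "DivideConquerResults":
        merged = self._merged_design()
        ea = run_ea(merged, self.ea_config)
        mask = tuple(int(i) for i in np.flatnonzero(ea.best_mask))
        step1 = train_lslda(merged, feature_mask=mask)
        rng = np.random.default_rng(self.ea_config.rng_seed + 1)
        bc = self._sub_threshold((ErrorClass.TYPE_B, ErrorClass.TYPE_C), rng)
        ef = self._sub_threshold((ErrorClass.TYPE_E, ErrorClass.TYPE_F), rng)
        return DivideConquerResults(self, step1, bc, ef, ea)


_MERGED_TO_ERROR = {
    MergedClass.CLEAN: ErrorClass.CLEAN,
    MergedClass.TYPE_A: ErrorClass.TYPE_A,
    MergedClass.TYPE_D: ErrorClass.TYPE_D,
}


@dataclass
class DivideConquerResults:
    model: DivideConquerModel
    step1: LinearClassifier
    bc_sub: ThresholdClassifier
    ef_sub: ThresholdClassifier
    ea: EAResult

    @property
    def selected_features(self) -> tuple[int, ...]:
        return self.ea.selected_features

    def predict_step1(self, patterns: np.ndarray) -> np.ndarray:
        """Merged-class labels 1..5."""
        return self.step1.predict(patterns)

    def predict(self, patterns: np.ndarray) -> np.ndarray:
        """Full-resolution labels 1..7 via the two-step decision."""
        patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
        merged = self.predict_step1(patterns)
        out = np.empty(merged.size, dtype=int)
        for i, m in enumerate(merged):
            m = MergedClass(m)
            if m is MergedClass.TYPE_BC:
                x = patterns[self.bc_sub.feature_index, i]
                out[i] = classify_by_threshold(x, self.bc_sub)
            elif m is MergedClass.TYPE_EF:
                x = patterns[self.ef_sub.feature_index, i]
                out[i] = classify_by_threshold(x, self.ef_sub)
            else:
                out[i] = int(_MERGED_TO_ERROR[m])
        return out

    def evaluate(self, test: LabeledDataset) -> EvaluationReport:
        """Full-resolution report plus per-step figures.

        The sub-classifier errors are computed on the *true* B/C (E/F)
        test samples, independent of step-1 decisions, mirroring how the
        two steps are validated separately.
        """
        pred = self.predict(test.patterns)
        base = evaluate(pred, test.labels, ERROR_CLASS_NAMES)
        merged_truth = np.array([int(merge_label(c)) for c in test.labels])
        merged_pred = self.predict_step1(test.patterns)
        step1_err = classification_error(merged_pred, merged_truth)
        step1_cm = confusion_matrix(merged_pred, merged_truth,
                                    len(MergedClass))
        subs = {}
        for tag, sub, pair in (
            ("bc", self.bc_sub, (ErrorClass.TYPE_B, ErrorClass.TYPE_C)),
            ("ef", self.ef_sub, (ErrorClass.TYPE_E, ErrorClass.TYPE_F)),
        ):
            sel = np.flatnonzero(np.isin(test.labels, [int(pair[0]), int(pair[1])]))
            if sel.size == 0:
                continue
            x = test.patterns[sub.feature_index, sel]
            sub_pred = np.array([classify_by_threshold(v, sub) for v in x])
            truth = test.labels[sel]
            # 2x2 confusion in (first, second) order of the pair
            remap = {int(pair[0]): 1, int(pair[1]): 2}
            cm = confusion_matrix(np.array([remap[p] for p in sub_pred]),
                                  np.array([remap[t] for t in truth]), 2)
            subs[tag] = (classification_error(sub_pred, truth), cm)
        return replace(
            base,
            step1_error_pct=step1_err,
            step1_confusion=step1_cm,
            bc_error_pct=subs.get("bc", (None, None))[0],
            bc_confusion=subs.get("bc", (None, None))[1],
            ef_error_pct=subs.get("ef", (None, None))[0],
            ef_confusion=subs.get("ef", (None, None))[1],
        )

    def summary(self) -> str:
        names = ", ".join(f"f{i}" for i in self.selected_features)
        return "\n".join([
            "Divide-and-conquer scheme (5 merged classes + 2 thresholds)",
            "===========================================================",
            f"  design samples   {self.model.design.n_samples}",
            f"  feature budget   {self.model.ea_config.n_feat}",
            f"  step-1 features  {names}",
            f"  CV error (EA)    {self.ea.best_fitness:.2f}%",
            f"  B/C split        f{self.bc_sub.feature_index + 1} "
            f"threshold {self.bc_sub.threshold:.6g}",
            f"  E/F split        f{self.ef_sub.feature_index + 1} "
            f"threshold {self.ef_sub.threshold:.6g}",
        ])

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "bisqc-divide-conquer-model",
            "version": 1,
            "step1": {
                "weights": self.step1.weights.tolist(),
                "feature_mask": list(self.step1.feature_mask),
                "class_names": list(self.step1.class_names),
            },
            "subs": {
                tag: {
                    "feature_index": sub.feature_index,
                    "threshold": sub.threshold,
                    "class_below": sub.class_below,
                    "class_above": sub.class_above,
                    "fold_thresholds": list(sub.fold_thresholds),
                }
                for tag, sub in (("bc", self.bc_sub), ("ef", self.ef_sub))
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def train_all_at_once(design: LabeledDataset, n_feat: int = 7,
                      ea_config: EAConfig | None = None,
                      rng_seed: int = 0) -> tuple[LinearClassifier, tuple[int, ...]]:
    """Functional wrapper: trained 7-class classifier and its 0-based mask."""
    res = AllAtOnceModel(design, n_feat, ea_config, rng_seed).fit()
    return res.classifier, res.classifier.feature_mask


def train_divide_conquer(design: LabeledDataset, n_feat: int = 7,
                         ea_config: EAConfig | None = None,
                         rng_seed: int = 0) -> DivideConquerResults:
    """Functional wrapper over ``DivideConquerModel(...).fit()``."""
    return DivideConquerModel(design, n_feat, ea_config, rng_seed).fit()


def predict_divide_conquer(model: DivideConquerResults,
                           features: np.ndarray) -> ErrorClass:
    """Full-resolution class of a single 31-feature vector."""
    label = model.predict(np.asarray(features, dtype=float).reshape(-1, 1))[0]
    return ErrorClass(int(label))
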