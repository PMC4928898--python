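"""Evolutionary wrapper feature selection.

Candidate solutions are binary masks over the 31 features.  Fitness is
the k-fold cross-validated LS-LDA classification error (%), computed on
fold assignments that are stratified by class, drawn once per run and
shared by every candidate so fitness comparisons are paired.  Evolution
follows truncation selection (top 10% survive as parents), uniform
crossover with per-gene mixing ratio 0.5 for the remaining 90%, repair
to the feature budget before evaluation, and mutation applied only to
duplicated candidates (never the best) until the population is distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import N_FEATURES
from .lslda import LabeledDataset, classification_error, train_lslda

__all__ = ["EAConfig", "EAResult", "repair", "stratified_folds", "cv_fitness",
           "fitness", "run_ea"]


@dataclass(frozen=True)
class EAConfig:
    """Evolutionary-algorithm settings.

    Defaults are the study conditions: population of 50 candidates, the
    best 10% kept as parents, uniform crossover with mixing ratio 0.5,
    100 generations, fitness from 5-fold cross-validation.
    """

    n_feat: int = 7
    population_size: int = 50
    parent_fraction: float = 0.10
    crossover_mix: float = 0.5
    generations: int = 100
    cv_folds: int = 5
    rng_seed: int = 0
    n_genes: int = N_FEATURES

    def __post_init__(self) -> None:
        if not 1 <= self.n_feat <= self.n_genes:
            raise ValueError(f"n_feat must be in 1..{self.n_genes}")
        if not 0 < self.parent_fraction < 1:
            raise ValueError("parent_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")


def repair(mask: np.ndarray, n_feat: int, rng: np.random.Generator) -> np.ndarray:
    """Enforce 1 <= popcount(mask) <= n_feat.

    Over-budget masks have randomly chosen set bits cleared one at a time;
    an all-zero mask gets one random bit set.  Feasible masks pass through
    unchanged (same object).
    """
    if n_feat < 1:
        raise ValueError("n_feat must be >= 1")
    ones = np.flatnonzero(mask)
    if ones.size == 0:
        out = mask.copy()
        out[rng.integers(mask.size)] = 1
        return out
    if ones.size <= n_feat:
        return mask
    out = mask.copy()
    drop = rng.choice(ones, size=ones.size - n_feat, replace=False)
    out[drop] = 0
    return out


def stratified_folds(labels: np.ndarray, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold index (0..k-1) per sample, stratified by class.

    Each class's samples are shuffled and dealt round-robin, so fold sizes
    per class differ by at most one.  Classes with fewer than ``k``
    samples are rejected.
    """
    labels = np.asarray(labels)
    fold = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValueError(f"class {c} has {idx.size} samples, fewer than {k} folds")
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def cv_fitness(mask: np.ndarray, data: LabeledDataset,
               fold_assignment: np.ndarray) -> float:
    """Mean over folds of the held-out LS-LDA classification error (%)."""
    sel = tuple(int(i) for i in np.flatnonzero(mask))
    if not sel:
        raise ValueError("empty feature mask")
    k = int(fold_assignment.max()) + 1
    errors = []
    for f in range(k):
        test = fold_assignment == f
        clf = train_lslda(data.subset(np.flatnonzero(~test)), feature_mask=sel)
        pred = clf.predict(data.patterns[:, test])
        errors.append(classification_error(pred, data.labels[test]))
    return float(np.mean(errors))


def fitness(mask: np.ndarray, data: LabeledDataset, folds: int,
            rng: np.random.Generator) -> float:
    """Convenience wrapper drawing a fresh stratified fold assignment."""
    return cv_fitness(mask, data, stratified_folds(data.labels, folds, rng))


@dataclass
class EAResult:
    """Best-ever mask with its fitness and the per-generation history."""

    best_mask: np.ndarray
    best_fitness: float
    history: pd.DataFrame = field(repr=False)

    @property
    def selected_features(self) -> tuple[int, ...]:
        """1-based indices of the selected features (f1..f31 numbering)."""
        return tuple(int(i) + 1 for i in np.flatnonzero(self.best_mask))

    def summary(self) -> str:
        names = ", ".join(f"f{i}" for i in self.selected_features)
        return (f"EA feature selection: best CV error {self.best_fitness:.2f}% "
                f"with features {{{names}}} "
                f"after {len(self.history)} generations")


def _dedupe(pop: np.ndarray, best_row: int, rng: np.random.Generator,
            n_feat: int) -> np.ndarray:
    """Mutate duplicated candidates (never the best) until all rows differ."""
    pop = pop.copy()
    while True:
        _, first = np.unique(pop, axis=0, return_index=True)
        keep = np.zeros(pop.shape[0], dtype=bool)
        keep[first] = True
        keep[best_row] = True
        # rows that duplicate an earlier (or the best) row get one bit flipped
        seen = {pop[i].tobytes() for i in np.flatnonzero(keep)}
        dirty = False
        for i in range(pop.shape[0]):
            if keep[i]:
                continue
            key = pop[i].tobytes()
            if key in seen:
                j = rng.integers(pop.shape[1])
                pop[i, j] ^= 1
                pop[i] = repair(pop[i], n_feat, rng)
                dirty = True
            seen.add(pop[i].tobytes())
        if not dirty:
            uniq = np.unique(pop, axis=0)
            if uniq.shape[0] == pop.shape[0]:
                return pop


def run_ea(data: LabeledDataset, config: EAConfig) -> EAResult:
    """Run the evolutionary search and return the best-ever candidate.

    All randomness (initial population, repair, fold shuffling, parent
    pairing, crossover, mutation) flows from ``config.rng_seed``.
    Fitness values are cached per mask within the run, which is sound
    because the fold assignment is fixed for the whole run.
    """
    rng = np.random.default_rng(config.rng_seed)
    folds = stratified_folds(data.labels, config.cv_folds, rng)
    n = config.population_size
    genes = config.n_genes
    cache: dict[bytes, float] = {}

    def evaluate(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = cv_fitness(mask, data, folds)
        return cache[key]

    pop = (rng.random((n, genes)) < 0.5).astype(np.int8)
    for i in range(n):
        pop[i] = repair(pop[i], config.n_feat, rng)

    n_parents = max(1, int(round(config.parent_fraction * n)))
    best_mask: np.ndarray | None = None
    best_fit = np.inf
    history = []

    for gen in range(config.generations):
        fits = np.array([evaluate(ind) for ind in pop])
        order = np.argsort(fits, kind="stable")
        if fits[order[0]] < best_fit:
            best_fit = float(fits[order[0]])
            best_mask = pop[order[0]].copy()
        history.append({"generation": gen + 1,
                        "best_error": best_fit,
                        "mean_error": float(fits.mean())})
        if gen == config.generations - 1:
            break
        parents = pop[order[:n_parents]]
        children = np.empty((n - n_parents, genes), dtype=np.int8)
        for i in range(children.shape[0]):
            a = rng.integers(n_parents)
            b = rng.integers(n_parents)
            while n_parents > 1 and b == a:
                b = rng.integers(n_parents)
            take_a = rng.random(genes) < config.crossover_mix
            children[i] = np.where(take_a, parents[a], parents[b])
            children[i] = repair(children[i], config.n_feat, rng)
        pop = np.vstack([parents, children])
        pop = _dedupe(pop, best_row=0, rng=rng, n_feat=config.n_feat)

    assert best_mask is not None
    return EAResult(best_mask, best_fit, pd.DataFrame(history))
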