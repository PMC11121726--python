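"""Best-first search over descriptor subsets.

Two subset merits are provided:

* ``cfs`` (default) — the correlation-based feature-selection heuristic

      merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

  where k = |S|, r_cf is the mean absolute Pearson correlation of each
  feature with the 0/1 class vector and r_ff the mean absolute pairwise
  Pearson correlation within S.  It rewards features correlated with the
  class and penalizes redundancy among the chosen features.

* ``wrapper_cv`` — mean accuracy of the package's own inverse-distance
  kNN classifier over seeded stratified cross-validation folds restricted
  to the subset.

The search keeps an open list of subsets ordered by merit, repeatedly
expands the best open subset by single-feature additions (and removals in
bidirectional mode), and stops after ``stall_limit`` consecutive
expansions that fail to improve the global best.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .labeling_split import ACTIVE

__all__ = [
    "SearchConfig",
    "FeatureSubset",
    "cfs_merit",
    "wrapper_cv_merit",
    "best_first_select",
]


@dataclass(frozen=True)
class SearchConfig:
    merit: Literal["cfs", "wrapper_cv"] = "cfs"
    direction: Literal["forward", "bidirectional"] = "forward"
    stall_limit: int = 5
    cv_folds: int = 5
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stall_limit < 1:
            raise ValueError("stall_limit must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class FeatureSubset:
    names: tuple[str, ...]
    merit_value: float


def _class_vector(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1.0 if lab == ACTIVE else 0.0 for lab in labels])


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r|; zero-variance input counts as zero correlation."""
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero-variance feature in subset; correlation treated as 0")
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def cfs_merit(
    subset: Sequence[str], matrix: pd.DataFrame, labels: Sequence[str]
) -> float:
    """Correlation-based merit of a feature subset (higher is better)."""
    names = list(subset)
    if not names:
        raise ValueError("subset must be non-empty")
    y = _class_vector(labels)
    cols = [matrix[name].to_numpy(dtype=float) for name in names]
    k = len(names)
    r_cf = float(np.mean([_abs_corr(c, y) for c in cols]))
    if k == 1:
        return r_cf
    r_ff = float(
        np.mean(
            [_abs_corr(cols[i], cols[j]) for i in range(k) for j in range(i + 1, k)]
        )
    )
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded stratified k-fold assignment; returns test-index arrays."""
    n = labels.size
    assignment = np.empty(n, dtype=int)
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return [np.where(assignment == f)[0] for f in range(n_folds)]


def wrapper_cv_merit(
    subset: Sequence[str],
    matrix: pd.DataFrame,
    labels: Sequence[str],
    config: SearchConfig | None = None,
) -> float:
    """Mean kNN cross-validated accuracy over the subset's columns."""
    from .readacross_model import KnnConfig, _knn_vote

    config = config or SearchConfig()
    names = list(subset)
    if not names:
        raise ValueError("subset must be non-empty")
    y = np.asarray(labels, dtype=object)
    if y.size < config.cv_folds:
        raise ValueError("fewer samples than cv folds")
    x = matrix[names].to_numpy(dtype=float)

    folds = None
    for attempt in range(3):
        rng = np.random.default_rng(config.seed + attempt)
        candidate = _stratified_folds(y, config.cv_folds, rng)
        if all(np.unique(y[np.setdiff1d(np.arange(y.size), f)]).size == 2 for f in candidate):
            folds = candidate
            break
    if folds is None:
        raise ValueError("could not build folds with both classes in every training part")

    knn = KnnConfig(k=min(config.knn_k, y.size - max(len(f) for f in folds)))
    correct = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        for q in test_idx:
            pred, _, _ = _knn_vote(x[train_idx], y[train_idx], x[q], knn)
            correct += pred == y[q]
    return correct / y.size


def _merit_fn(config: SearchConfig, matrix: pd.DataFrame, labels: Sequence[str]):
    if config.merit != "cfs":
        return lambda names: wrapper_cv_merit(names, matrix, labels, config)

    # precompute |corr| tables once; equals cfs_merit on every subset
    x = matrix.to_numpy(dtype=float)
    y = _class_vector(labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(np.column_stack([x, y]), rowvar=False)
    full = np.abs(np.nan_to_num(full, nan=0.0))
    r_cf_all = full[:-1, -1]
    r_ff_all = full[:-1, :-1]
    pos = {str(c): i for i, c in enumerate(matrix.columns)}

    def merit(names) -> float:
        idx = [pos[n] for n in names]
        k = len(idx)
        r_cf = float(r_cf_all[idx].mean())
        if k == 1:
            return r_cf
        sub = r_ff_all[np.ix_(idx, idx)]
        r_ff = float((sub.sum() - k) / (k * (k - 1)))
        return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)

    return merit


def best_first_select(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    config: SearchConfig | None = None,
    trace: list | None = None,
) -> FeatureSubset:
    """Best-first subset search; deterministic given (matrix, labels, config).

    Returns the globally best subset found.  An empty subset (merit 0) is
    legal when no single feature improves on it.  Pass a list as ``trace``
    to record (subset, merit) per expansion.
    """
    config = config or SearchConfig()
    if matrix.shape[1] < 1:
        raise ValueError("need at least one candidate column")
    evaluate = _merit_fn(config, matrix, labels)
    all_names = tuple(str(c) for c in matrix.columns)
    name_pos = {n: i for i, n in enumerate(all_names)}

    cache: dict[frozenset, float] = {frozenset(): 0.0}

    def merit_of(names: frozenset) -> float:
        if names not in cache:
            cache[names] = evaluate(tuple(sorted(names, key=name_pos.get)))
        return cache[names]

    # heap entries: (-merit, insertion order, subset); order makes ties FIFO
    counter = 0
    open_heap: list[tuple[float, int, frozenset]] = [(0.0, counter, frozenset())]
    closed: set[frozenset] = set()
    best_set: frozenset = frozenset()
    best_merit = 0.0
    stall = 0

    while open_heap and stall < config.stall_limit:
        _, _, current = heapq.heappop(open_heap)
        if current in closed:
            continue
        closed.add(current)

        improved = False
        children = [current | {n} for n in all_names if n not in current]
        if config.direction == "bidirectional":
            children += [current - {n} for n in current]
        for child in children:
            if not child or child in closed:
                continue
            m = merit_of(child)
            counter += 1
            heapq.heappush(open_heap, (-m, counter, child))
            if m > best_merit + 1e-12:
                best_merit = m
                best_set = child
                improved = True
        if trace is not None:
            trace.append((tuple(sorted(current, key=name_pos.get)), merit_of(current)))
        stall = 0 if improved else stall + 1

    names = tuple(sorted(best_set, key=name_pos.get))
    return FeatureSubset(names=names, merit_value=best_merit)
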