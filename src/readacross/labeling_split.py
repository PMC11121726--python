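"""Activity labelling from EC50 and rational train/test splitting.

EC50 (the agonist concentration giving half-maximal effect, in uM) is a
continuous potency measure; a binary active/inactive label is derived by
two-means clustering of log10(EC50).  In one dimension with k = 2 the
globally optimal partition is a contiguous split of the sorted values, so
it is found exactly by scanning the n-1 split points — no random
initialization, no seed dependence.  Lower EC50 means higher potency, so
the cluster with the lower log-EC50 centroid is the active class.

Train/test partitioning uses the Kennard–Stone max–min algorithm: seed the
training set with the two most distant points, then repeatedly add the
point whose minimum distance to the current training set is largest.  The
result is deterministic and spans descriptor space uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

ACTIVE = "active"
INACTIVE = "inactive"

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "LabelingResult",
    "SplitConfig",
    "SplitResult",
    "label_by_two_means",
    "kennard_stone_split",
]


@dataclass(frozen=True)
class LabelingResult:
    """Two-means labelling of log10(EC50) values.

    ``centroids`` are on the log10(EC50/uM) scale, ordered
    (active, inactive); the active centroid is always the lower one.
    """

    labels: tuple[str, ...]
    centroids: tuple[float, float]
    cluster_sizes: tuple[int, int]


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def label_by_two_means(ec50_uM) -> LabelingResult:
    """Exact 1-D two-means clustering of log10(EC50/uM).

    Scans all n-1 contiguous split points of the sorted log values and
    keeps the partition minimizing the within-cluster sum of squares; this
    is the global 2-means optimum in one dimension.

    Parameters
    ----------
    ec50_uM : sequence of positive floats
        One EC50 per compound, micromolar.

    Returns
    -------
    LabelingResult with one label per input value, in input order.
    """
    values = np.asarray(ec50_uM, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least two EC50 values")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("EC50 values must be positive and finite")
    log_values = np.log10(values)
    if np.all(log_values == log_values[0]):
        raise ValueError("degenerate potency distribution: all EC50 identical")

    order = np.argsort(log_values, kind="stable")
    x = log_values[order]
    n = x.size
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)

    def wcss(lo: int, hi: int) -> float:  # half-open [lo, hi)
        s = csum[hi - 1] - (csum[lo - 1] if lo else 0.0)
        s2 = csum2[hi - 1] - (csum2[lo - 1] if lo else 0.0)
        return s2 - s * s / (hi - lo)

    best_split, best_cost = 1, math.inf
    for split in range(1, n):
        cost = wcss(0, split) + wcss(split, n)
        if cost < best_cost - 1e-15:
            best_cost = cost
            best_split = split

    low_idx = order[:best_split]  # lower log-EC50 => more potent => active
    labels = np.full(n, INACTIVE, dtype=object)
    labels[low_idx] = ACTIVE
    active_centroid = float(log_values[low_idx].mean())
    inactive_centroid = float(log_values[order[best_split:]].mean())
    return LabelingResult(
        labels=tuple(labels),
        centroids=(active_centroid, inactive_centroid),
        cluster_sizes=(int(best_split), int(n - best_split)),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def kennard_stone_split(
    matrix: pd.DataFrame, config: SplitConfig | None = None
) -> SplitResult:
    """Kennard–Stone max–min split on Euclidean distances.

    ``matrix`` rows are compounds (index = compound ids); all current
    columns enter the metric, so pass the standardized matrix.  The
    training-set size is round-half-up(train_fraction * n).  Ties in the
    max–min criterion are broken by lowest row index, which makes the
    selection fully deterministic.
    """
    config = config or SplitConfig()
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to split")
    n_train = _round_half_up(config.train_fraction * n)
    if n_train < 2:
        raise ValueError(f"train_fraction {config.train_fraction} yields fewer than 2 training rows")

    x = matrix.to_numpy(dtype=float)
    dist = squareform(pdist(x, metric="euclidean"))

    # seed: the pair at maximal distance, ties by lowest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = int(np.argmax(flat))  # argmax returns first (lowest-index) max
    i0, j0 = int(iu[0][best]), int(iu[1][best])

    selected = [i0, j0]
    remaining = np.ones(n, dtype=bool)
    remaining[[i0, j0]] = False
    min_dist = np.minimum(dist[i0], dist[j0])
    while len(selected) < n_train:
        cand = np.where(remaining)[0]
        pick = int(cand[np.argmax(min_dist[cand])])
        selected.append(pick)
        remaining[pick] = False
        min_dist = np.minimum(min_dist, dist[pick])

    ids = [str(i) for i in matrix.index]
    train_ids = tuple(ids[i] for i in selected)
    test_ids = tuple(ids[i] for i in range(n) if i not in set(selected))
    return SplitResult(train_ids=train_ids, test_ids=test_ids)
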