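"""Inverse-distance-weighted kNN read-across with a distance applicability domain.

The classifier is deliberately transparent: a query compound is assigned
the class of its k nearest training compounds in standardized descriptor
space (Euclidean metric), each neighbour voting with weight 1/distance,
and the neighbours themselves are reported as the read-across evidence.

Reliability is judged by a distance-based applicability domain (APD).
From all pairwise Euclidean distances among training compounds, those not
exceeding their grand mean are retained; with d_bar and sigma the mean and
sample standard deviation of the retained distances, the threshold is

    APD = z * sigma + d_bar        (z defaults to 0.5)

A prediction is flagged reliable when the query's distance to its nearest
training compound is at or below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .feature_selection import SearchConfig, best_first_select
from .labeling_split import (
    ACTIVE,
    INACTIVE,
    SplitConfig,
    kennard_stone_split,
    label_by_two_means,
)
from .preprocess import (
    PreprocessConfig,
    StandardizationParams,
    apply_standardizer,
    drop_redundant_columns,
    fit_standardizer,
    variance_filter,
)

BUNDLE_SCHEMA_VERSION = "readacross-bundle-1"
EXACT_MATCH_TOL = 1e-12

__all__ = [
    "KnnConfig",
    "ApdModel",
    "Prediction",
    "ModelBundle",
    "PipelineConfig",
    "compute_apd",
    "knn_predict",
    "predict_table",
    "train_readacross",
]


@dataclass(frozen=True)
class KnnConfig:
    """k, vote weighting and neighbour-reporting options.

    ``report_extra_neighbor`` emits k+1 neighbours in reports while still
    voting on k (a compatibility option for consumers expecting one spare
    neighbour in the listing).
    """

    k: int = 5
    weighting: Literal["inverse_distance", "uniform"] = "inverse_distance"
    report_extra_neighbor: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weighting not in ("inverse_distance", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class ApdModel:
    """Distance applicability domain: threshold = z * sigma + d_bar."""

    z: float
    d_bar: float
    sigma: float
    threshold: float

    def __post_init__(self) -> None:
        for name in ("z", "d_bar", "sigma", "threshold"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if abs(self.threshold - (self.z * self.sigma + self.d_bar)) > 1e-12:
            raise ValueError("threshold != z * sigma + d_bar")


@dataclass(frozen=True)
class Prediction:
    query_id: str
    predicted_class: str
    neighbors: tuple[tuple[str, float], ...]  # (train id, distance), ascending
    vote_weights: dict
    domain_distance: float
    apd_threshold: float
    reliable: bool


@dataclass(frozen=True)
class ModelBundle:
    """Everything needed to predict: features, scaling, training data, APD."""

    selected_features: tuple[str, ...]
    standardization: StandardizationParams
    train_matrix: np.ndarray  # standardized, rows x selected_features
    train_ids: tuple[str, ...]
    train_labels: tuple[str, ...]
    knn_config: KnnConfig
    apd: ApdModel
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.train_matrix, dtype=float)
        object.__setattr__(self, "train_matrix", m)
        if m.ndim != 2 or m.shape[1] != len(self.selected_features):
            raise ValueError("train_matrix column count must equal |selected_features|")
        if not (len(self.train_ids) == len(self.train_labels) == m.shape[0]):
            raise ValueError("train_ids, train_labels and train_matrix rows must agree")
        if self.knn_config.k > m.shape[0]:
            raise ValueError("k exceeds number of training rows")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end training configuration; defaults are the recommended ones.

    ``standardization_scope``: ``train_only`` refits the standardizer on
    the training partition (leakage-free); ``full`` keeps the fit on the
    complete dataset, the ordering some legacy workflows use.
    ``apd_retain``: which side of the mean pairwise distance is kept when
    estimating the domain threshold (see :func:`compute_apd`).
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    z: float = 0.5
    standardization_scope: Literal["train_only", "full"] = "train_only"
    apd_retain: Literal["below_mean", "above_mean"] = "below_mean"


def compute_apd(
    train_matrix, z: float = 0.5, retain: Literal["below_mean", "above_mean"] = "below_mean"
) -> ApdModel:
    """Fit the distance-based applicability domain on training rows.

    All n(n-1)/2 pairwise Euclidean distances are computed and their mean
    m taken.  With ``retain="below_mean"`` (default, the convention of the
    distance-APD method family) distances <= m are kept; ``"above_mean"``
    keeps distances >= m instead.  d_bar and sigma are the mean and sample
    sd (0 if fewer than 2 retained) of the kept distances.
    """
    x = np.asarray(
        train_matrix.to_numpy() if isinstance(train_matrix, pd.DataFrame) else train_matrix,
        dtype=float,
    )
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two training rows")
    if z < 0:
        raise ValueError("z must be >= 0")
    d = pdist(x, metric="euclidean")
    m = float(d.mean())
    if np.all(d == 0.0):
        warnings.warn("all pairwise training distances are zero; APD threshold is 0")
        return ApdModel(z=z, d_bar=0.0, sigma=0.0, threshold=0.0)
    kept = d[d <= m] if retain == "below_mean" else d[d >= m]
    d_bar = float(kept.mean())
    sigma = float(kept.std(ddof=1)) if kept.size >= 2 else 0.0
    return ApdModel(z=z, d_bar=d_bar, sigma=sigma, threshold=z * sigma + d_bar)


def _knn_vote(
    train_x: np.ndarray, train_y: np.ndarray, query: np.ndarray, config: KnnConfig
):
    """Core vote: returns (class, [(row_index, distance), ...] of length k,
    vote weights per class).  Distance ties break on lowest row index; an
    exact match (distance < 1e-12) decides the class alone."""
    d = np.linalg.norm(train_x - query, axis=1)
    order = np.argsort(d, kind="stable")
    k = min(config.k, train_x.shape[0])
    nearest = [(int(i), float(d[i])) for i in order[:k]]

    if nearest[0][1] < EXACT_MATCH_TOL:
        cls = str(train_y[nearest[0][0]])
        weights = {ACTIVE: 0.0, INACTIVE: 0.0}
        weights[cls] = float("inf")
        return cls, nearest, weights

    weights = {ACTIVE: 0.0, INACTIVE: 0.0}
    for i, dist in nearest:
        w = 1.0 / dist if config.weighting == "inverse_distance" else 1.0
        weights[str(train_y[i])] += w
    # tie -> inactive: the conservative call for a potency screen
    cls = ACTIVE if weights[ACTIVE] > weights[INACTIVE] else INACTIVE
    return cls, nearest, weights


def knn_predict(model: ModelBundle, query_row, query_id: str = "query") -> Prediction:
    """Classify one standardized query vector against the bundle."""
    q = np.asarray(query_row, dtype=float).ravel()
    if q.size != len(model.selected_features):
        raise ValueError(
            f"query has {q.size} values but the model uses "
            f"{len(model.selected_features)} features"
        )
    if not np.all(np.isfinite(q)):
        raise ValueError("query contains non-finite values")

    labels = np.asarray(model.train_labels, dtype=object)
    cls, nearest, weights = _knn_vote(model.train_matrix, labels, q, model.knn_config)
    domain_distance = float(
        np.linalg.norm(model.train_matrix - q, axis=1).min()
    )

    n_report = model.knn_config.k + (1 if model.knn_config.report_extra_neighbor else 0)
    if n_report > len(nearest):
        d = np.linalg.norm(model.train_matrix - q, axis=1)
        order = np.argsort(d, kind="stable")
        nearest = [(int(i), float(d[i])) for i in order[: min(n_report, d.size)]]
    neighbors = tuple(
        (str(model.train_ids[i]), dist) for i, dist in nearest[:n_report]
    )
    return Prediction(
        query_id=str(query_id),
        predicted_class=cls,
        neighbors=neighbors,
        vote_weights=weights,
        domain_distance=domain_distance,
        apd_threshold=model.apd.threshold,
        reliable=domain_distance <= model.apd.threshold,
    )


def predict_table(model: ModelBundle, descriptors: pd.DataFrame) -> list[Prediction]:
    """Standardize raw descriptor rows with the bundle's parameters and
    classify each; rows must cover every selected feature."""
    std = apply_standardizer(descriptors, model.standardization)
    return [
        knn_predict(model, std.loc[idx].to_numpy(), query_id=str(idx))
        for idx in std.index
    ]


def train_readacross(
    compounds: Sequence,
    descriptors: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> ModelBundle:
    """Run the full training pipeline and assemble a model bundle.

    Stages, in order: column pruning -> variance filter -> two-means
    potency labelling -> standardization -> Kennard-Stone split ->
    best-first feature selection on the training partition -> APD fit on
    the selected, standardized training matrix.

    ``compounds`` is a sequence of records with ``compound_id`` and
    ``ec50_uM`` attributes (EC50 required for every compound);
    ``descriptors`` is indexed by the same ids.  The held-out test
    partition (ids and labels) is recorded in the bundle provenance for
    later validation; its rows never influence feature selection, the
    standardizer (default scope) or the APD.
    """
    config = config or PipelineConfig()
    ids = [str(c.compound_id) for c in compounds]
    missing_ec50 = [c.compound_id for c in compounds if getattr(c, "ec50_uM", None) is None]
    if missing_ec50:
        raise ValueError(f"labeling: EC50 missing for {', '.join(map(str, missing_ec50))}")
    if list(map(str, descriptors.index)) != ids:
        descriptors = descriptors.loc[ids]

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    pruned, log1 = stage("prune", drop_redundant_columns, descriptors, config.preprocess)
    filtered, log2 = stage("variance_filter", variance_filter, pruned, config.preprocess)

    labeling = stage(
        "labeling", label_by_two_means, [float(c.ec50_uM) for c in compounds]
    )
    labels = dict(zip(ids, labeling.labels))

    full_params = stage("standardize", fit_standardizer, filtered)
    std_full = apply_standardizer(filtered, full_params)
    split = stage("split", kennard_stone_split, std_full, config.split)

    train_raw = filtered.loc[list(split.train_ids)]
    if config.standardization_scope == "train_only":
        params = stage("standardize", fit_standardizer, train_raw)
    else:
        params = full_params
    train_std = apply_standardizer(train_raw, params)
    train_labels = [labels[i] for i in split.train_ids]

    subset = stage("feature_selection", best_first_select, train_std, train_labels, config.search)
    if not subset.names:
        raise ValueError("feature_selection: produced an empty subset")

    sel = list(subset.names)
    sel_idx = [params.column_names.index(c) for c in sel]
    sel_params = StandardizationParams(
        column_names=tuple(sel),
        mean=tuple(params.mean[i] for i in sel_idx),
        sd=tuple(params.sd[i] for i in sel_idx),
    )
    train_sel = train_std[sel].to_numpy(dtype=float)
    apd = stage("apd", compute_apd, train_sel, config.z, config.apd_retain)

    provenance = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "n_compounds": len(ids),
        "test_ids": list(split.test_ids),
        "labels": labels,
        "centroids": list(labeling.centroids),
        "cluster_sizes": list(labeling.cluster_sizes),
        "candidate_features": [str(c) for c in filtered.columns],
        "removed_columns": log1.entries + log2.entries,
        "feature_merit": subset.merit_value,
        "standardization_scope": config.standardization_scope,
        "apd_retain": config.apd_retain,
    }
    return ModelBundle(
        selected_features=tuple(sel),
        standardization=sel_params,
        train_matrix=train_sel,
        train_ids=tuple(split.train_ids),
        train_labels=tuple(train_labels),
        knn_config=config.knn,
        apd=apd,
        provenance=provenance,
    )
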