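"""Descriptor-matrix pruning and Gaussian (z-score) standardization.

Molecular-descriptor tables are wide and redundant: many columns are
near-constant over a congeneric series, and some descriptor families emit
bit-identical columns.  Before any distance-based modelling the matrix is
pruned (near-constant columns, duplicated columns, low-variance columns)
and each surviving column is standardized to zero mean and unit standard
deviation so that Euclidean distances are not dominated by scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "StandardizationParams",
    "drop_redundant_columns",
    "variance_filter",
    "fit_standardizer",
    "apply_standardizer",
    "inverse_standardizer",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Pruning thresholds.

    near_constant_fraction
        A column is dropped when its single most frequent value accounts for
        *more than* this fraction of rows (strict inequality).  Default 0.8.
    variance_threshold_mode
        ``fraction_of_max``: drop columns with variance below
        ``variance_threshold`` x (largest column variance in the table).
        ``absolute``: compare variance to ``variance_threshold`` directly.
    variance_threshold
        Default 0.20 (i.e. a 20 % low-variance filter in fraction mode).
    """

    near_constant_fraction: float = 0.8
    variance_threshold_mode: Literal["fraction_of_max", "absolute"] = "fraction_of_max"
    variance_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.near_constant_fraction <= 1.0:
            raise ValueError("near_constant_fraction must be in (0, 1]")
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be >= 0")
        if self.variance_threshold_mode not in ("fraction_of_max", "absolute"):
            raise ValueError(f"unknown mode {self.variance_threshold_mode!r}")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column sample mean and sample sd (n-1 denominator)."""

    column_names: tuple[str, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.column_names) == len(self.mean) == len(self.sd):
            raise ValueError("column_names, mean and sd must have equal length")
        for name, s in zip(self.column_names, self.sd):
            if not s > 0:
                raise ValueError(f"standard deviation must be > 0 (column {name!r})")


@dataclass
class RemovalLog:
    """Which columns were dropped, by which rule, at what statistic value."""

    entries: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, column: str, rule: str, value: float) -> None:
        self.entries.append((column, rule, value))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["column_name", "rule", "value"])


def _check_table(table: pd.DataFrame) -> None:
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("descriptor table is empty")


def drop_redundant_columns(
    table: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, RemovalLog]:
    """Remove near-constant columns and duplicated columns.

    Two rules, applied in column order:

    * near-constant — the modal value covers strictly more than
      ``near_constant_fraction`` of the rows;
    * duplicate — the column is bit-identical to an earlier kept column
      (the first occurrence survives).

    Raises ``ValueError`` if nothing survives.
    """
    config = config or PreprocessConfig()
    _check_table(table)
    n = len(table)
    log = RemovalLog()
    keep: list[str] = []
    seen: list[np.ndarray] = []
    for name in table.columns:
        col = table[name].to_numpy()
        modal = pd.Series(col).value_counts(dropna=False).iloc[0]
        frac = modal / n
        if frac > config.near_constant_fraction:
            log.add(name, "near_constant", float(frac))
            continue
        dup_of = next(
            (keep[i] for i, prev in enumerate(seen) if np.array_equal(prev, col)), None
        )
        if dup_of is not None:
            log.add(name, f"duplicate_of:{dup_of}", 1.0)
            continue
        keep.append(name)
        seen.append(col)
    if not keep:
        raise ValueError("no descriptors survive pruning")
    return table[keep], log


def variance_filter(
    table: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, RemovalLog]:
    """Drop low-variance columns (sample variance, n-1 denominator).

    In ``fraction_of_max`` mode the cutoff is relative to the largest column
    variance in the table; in ``absolute`` mode it is the threshold itself.
    """
    config = config or PreprocessConfig()
    _check_table(table)
    variances = table.var(axis=0, ddof=1)
    if config.variance_threshold_mode == "fraction_of_max":
        cutoff = config.variance_threshold * float(variances.max())
    else:
        cutoff = config.variance_threshold
    log = RemovalLog()
    keep = []
    for name in table.columns:
        v = float(variances[name])
        if v < cutoff:
            log.add(name, "low_variance", v)
        else:
            keep.append(name)
    if not keep:
        raise ValueError("no descriptors survive pruning")
    return table[keep], log


def fit_standardizer(table: pd.DataFrame) -> StandardizationParams:
    """Fit per-column mean/sd.  Errors on any zero-variance column."""
    _check_table(table)
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    zero = [str(c) for c in table.columns if not sd[c] > 0]
    if zero:
        raise ValueError(f"zero standard deviation in column(s): {', '.join(zero)}")
    return StandardizationParams(
        column_names=tuple(str(c) for c in table.columns),
        mean=tuple(float(m) for m in mean),
        sd=tuple(float(s) for s in sd),
    )


def apply_standardizer(
    table: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    """Return (x - mean) / sd restricted to ``params.column_names`` in order."""
    missing = [c for c in params.column_names if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    sub = table[list(params.column_names)]
    mean = np.asarray(params.mean)
    sd = np.asarray(params.sd)
    return (sub - mean) / sd


def inverse_standardizer(
    table: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    """Undo :func:`apply_standardizer`: x * sd + mean."""
    missing = [c for c in params.column_names if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    sub = table[list(params.column_names)]
    return sub * np.asarray(params.sd) + np.asarray(params.mean)
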