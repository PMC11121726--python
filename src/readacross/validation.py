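"""Binary-classification validation: confusion-matrix statistics and
Y-randomization (response scrambling).

The active class is the positive class throughout.  Any statistic whose
denominator is zero is reported as ``None`` (undefined), never coerced to
zero.  Percentages round half-up to one decimal and coefficients to three
decimals when formatted, matching the usual reporting precision for these
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .labeling_split import ACTIVE, INACTIVE
from .readacross_model import ModelBundle, predict_table

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "YRandomizationResult",
    "confusion_from_predictions",
    "classification_metrics",
    "evaluate_bundle",
    "y_randomization",
    "round_half_up",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The six statistics; ``None`` marks an undefined (0/0) value."""

    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    f1: float | None
    mcc: float | None
    kappa: float | None

    def rounded(self) -> dict:
        """Percentages at one decimal, coefficients at three decimals."""

        def pct(v):
            return None if v is None else round_half_up(100.0 * v, 1)

        def coef(v):
            return None if v is None else round_half_up(v, 3)

        return {
            "accuracy_pct": pct(self.accuracy),
            "sensitivity_pct": pct(self.sensitivity),
            "precision_pct": pct(self.precision),
            "f1_pct": pct(self.f1),
            "mcc": coef(self.mcc),
            "kappa": coef(self.kappa),
        }


@dataclass(frozen=True)
class YRandomizationResult:
    repetitions: int
    seed: int
    original: MetricsReport
    randomized: tuple[MetricsReport, ...]


def confusion_from_predictions(
    actual: Sequence[str], predicted: Sequence[str]
) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with ``active`` as the positive class."""
    if len(actual) != len(predicted) or len(actual) < 1:
        raise ValueError("actual and predicted must have equal length >= 1")
    valid = {ACTIVE, INACTIVE}
    bad = sorted({t for t in list(actual) + list(predicted) if t not in valid})
    if bad:
        raise ValueError(f"unknown class token(s): {', '.join(map(repr, bad))}")
    tp = fn = fp = tn = 0
    for a, p in zip(actual, predicted):
        if a == ACTIVE:
            tp += p == ACTIVE
            fn += p == INACTIVE
        else:
            fp += p == ACTIVE
            tn += p == INACTIVE
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, precision, F1, MCC and Cohen's kappa.

    Kappa is computed as (p_o - p_e) / (1 - p_e) with the usual expected
    agreement p_e; this is algebraically identical to the two-by-two
    closed form 2(TP*TN - FP*FN)/((TP+FP)(FP+TN) + (TP+FN)(TN+FN)).
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    total = cm.total
    accuracy = _ratio(tp + tn, total)
    sensitivity = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den

    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (total * total)
    kappa = None if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        mcc=mcc,
        kappa=kappa,
    )


def _test_partition(bundle: ModelBundle, descriptors: pd.DataFrame):
    prov = bundle.provenance
    test_ids = [str(i) for i in prov.get("test_ids", [])]
    if not test_ids:
        raise ValueError("bundle provenance holds no test partition")
    labels = prov["labels"]
    actual = [labels[i] for i in test_ids]
    table = descriptors.loc[test_ids]
    return test_ids, actual, table


def evaluate_bundle(bundle: ModelBundle, descriptors: pd.DataFrame) -> MetricsReport:
    """Metrics of the bundle on its held-out test partition (raw
    descriptors in, standardization applied with the bundle's params)."""
    _, actual, table = _test_partition(bundle, descriptors)
    predicted = [p.predicted_class for p in predict_table(bundle, table)]
    return classification_metrics(confusion_from_predictions(actual, predicted))


def y_randomization(
    bundle: ModelBundle,
    descriptors: pd.DataFrame,
    repetitions: int = 5,
    seed: int = 0,
    permute: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> YRandomizationResult:
    """Response scrambling: retrain on permuted training labels, score on
    the untouched test set.

    The selected features, standardization and APD are held fixed; only
    the training labels are permuted (with a generator seeded from
    ``seed``), so each repetition measures how much of the original
    performance survives when the structure-activity link is severed.  A
    robust model's randomized accuracies collapse toward chance.
    ``permute`` may override the permutation source (mainly for tests).
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    _, actual, test_table = _test_partition(bundle, descriptors)
    original = evaluate_bundle(bundle, descriptors)

    rng = np.random.default_rng(seed)
    draw = permute or (lambda g, n: g.permutation(n))
    labels = np.asarray(bundle.train_labels, dtype=object)
    reports = []
    for _ in range(repetitions):
        perm = np.asarray(draw(rng, labels.size))
        shuffled = replace(bundle, train_labels=tuple(labels[perm]))
        predicted = [p.predicted_class for p in predict_table(shuffled, test_table)]
        reports.append(
            classification_metrics(confusion_from_predictions(actual, predicted))
        )
    return YRandomizationResult(
        repetitions=repetitions,
        seed=seed,
        original=original,
        randomized=tuple(reports),
    )
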