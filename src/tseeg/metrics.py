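"""Confusion-matrix construction and derived binary-classification scores.

Scores follow the usual definitions: accuracy = (TP + TN) / total,
sensitivity (recall) = TP / (TP + FN), specificity = TN / (TN + FP), and the
F-score is the F1 statistic, the harmonic mean of precision and sensitivity.
A score whose denominator is zero is *undefined* and reported as NaN rather
than silently coerced to zero — small per-channel test sets can easily empty
one predicted class — and summaries exclude undefined values while recording
how many were excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion-matrix counts must be nonnegative")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    true_labels: list[str], predicted: list[str], positive_class: str
) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix with the stated positive class."""
    if len(true_labels) != len(predicted):
        raise ValueError("true and predicted label lists differ in length")
    if len(true_labels) == 0:
        raise ValueError("cannot tally an empty label list")
    classes = set(true_labels) | set(predicted)
    if len(classes) > 2:
        raise ValueError(f"binary metrics need <= 2 classes, got {sorted(classes)}")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted):
        if p == positive_class:
            if t == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_class:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); NaN when no positive samples exist."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else math.nan


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP); NaN when no negative samples exist."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else math.nan


def f_score(cm: ConfusionMatrix) -> float:
    """F1: harmonic mean of precision and sensitivity.

    Zero when TP = 0 but errors exist; NaN only in the fully degenerate case
    of no positive predictions and no positive truths.
    """
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        return math.nan
    return 2 * cm.tp / denom


_SCORES = {
    "accuracy": accuracy,
    "sensitivity": sensitivity,
    "specificity": specificity,
    "f_score": f_score,
}


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregate of repeated evaluations: per-repetition matrices plus the
    mean and max of each score (undefined repetitions excluded and counted)."""

    matrices: tuple[ConfusionMatrix, ...]
    mean_accuracy: float
    max_accuracy: float
    mean_f_score: float
    max_f_score: float
    mean_sensitivity: float
    mean_specificity: float
    undefined_counts: dict[str, int]

    @property
    def n_repetitions(self) -> int:
        return len(self.matrices)

    def to_json(self) -> str:
        doc = {
            "matrices": [asdict(m) for m in self.matrices],
            "undefined_counts": self.undefined_counts,
        }
        for k in (
            "mean_accuracy",
            "max_accuracy",
            "mean_f_score",
            "max_f_score",
            "mean_sensitivity",
            "mean_specificity",
        ):
            v = getattr(self, k)
            doc[k] = None if math.isnan(v) else v
        return json.dumps(doc, indent=1)


def summarize(matrices: list[ConfusionMatrix]) -> EvaluationSummary:
    """Mean and maximum of each score across repetitions."""
    if not matrices:
        raise ValueError("cannot summarize an empty matrix list")
    stats: dict[str, list[float]] = {}
    undefined: dict[str, int] = {}
    for name, fn in _SCORES.items():
        vals = [fn(m) for m in matrices]
        defined = [v for v in vals if not math.isnan(v)]
        undefined[name] = len(vals) - len(defined)
        stats[name] = defined
    def _mean(name: str) -> float:
        return sum(stats[name]) / len(stats[name]) if stats[name] else math.nan
    def _max(name: str) -> float:
        return max(stats[name]) if stats[name] else math.nan
    return EvaluationSummary(
        matrices=tuple(matrices),
        mean_accuracy=_mean("accuracy"),
        max_accuracy=_max("accuracy"),
        mean_f_score=_mean("f_score"),
        max_f_score=_max("f_score"),
        mean_sensitivity=_mean("sensitivity"),
        mean_specificity=_mean("specificity"),
        undefined_counts=undefined,
    )
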