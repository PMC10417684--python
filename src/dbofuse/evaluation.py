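"""Per-class one-vs-rest evaluation stack.

For a K-class confusion matrix every class is scored one-vs-rest: that class
is the positive, everything else the negative, giving per-class TP/FP/FN/TN
and from them

* accuracy     = 100 (TP + TN) / N          (one-vs-rest, so it varies by class)
* precision    = 100 TP / (TP + FP)
* sensitivity  = 100 TP / (TP + FN)         (recall)
* specificity  = 100 TN / (TN + FP)
* F-score      = 2 prec sens / (prec + sens)

all reported as percentages.  Macro averages are unweighted arithmetic means
over classes.  Values are kept at full precision internally and rounded
half-up to two decimals only for display.  The micro classification error
rate (100 x misclassified / total) is the fitness minimized by the DBO
hyperparameter search.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "EvaluationReport",
    "confusion_matrix",
    "per_class_metrics",
    "macro_average",
    "classification_error_rate",
    "round_half_up",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f_score")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero at the given decimal (display rule)."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = number of samples of true class i predicted as class j."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_names = tuple(self.class_names)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K class names")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_names, name="true"),
            columns=pd.Index(self.class_names, name="predicted"),
        )


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    """Build a :class:`ConfusionMatrix` with a fixed class order."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists must have equal length")
    if len(true_labels) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    known = set(class_names)
    for lab in (*true_labels, *predicted_labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}; expected one of {sorted(known)}")
    counts = _sk_confusion_matrix(
        true_labels, predicted_labels, labels=list(class_names)
    )
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest metric table (percent, full precision) plus
    unweighted macro averages.  ``undefined`` lists (class, metric) pairs that
    could not be computed (e.g. precision with no predicted positives); these
    are excluded from their macro mean."""

    table: pd.DataFrame
    macro: pd.Series
    undefined: tuple[tuple[str, str], ...] = ()

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        """Display table with half-up rounding and a macro ('Average') row."""
        out = self.table.map(lambda v: round_half_up(v, decimals) if np.isfinite(v) else v)
        out.loc["Average"] = [round_half_up(v, decimals) for v in self.macro]
        return out


def per_class_metrics(matrix: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest accuracy/precision/sensitivity/specificity/F-score per class.

    A class with no predicted positives has undefined precision (and F-score);
    those entries are NaN, flagged in ``undefined``, excluded from the macro
    mean, and a warning is emitted.
    """
    counts = matrix.counts
    n = matrix.total
    if n == 0:
        raise ValueError("confusion matrix is empty")
    rows = {}
    undefined: list[tuple[str, str]] = []
    for i, name in enumerate(matrix.class_names):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = n - tp - fn - fp
        accuracy = 100.0 * (tp + tn) / n
        sensitivity = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
        specificity = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
        if tp + fp > 0:
            precision = 100.0 * tp / (tp + fp)
        else:
            precision = np.nan
            undefined.append((name, "precision"))
            warnings.warn(
                f"class {name!r} has no predicted positives; precision undefined",
                stacklevel=2,
            )
        if np.isfinite(precision) and np.isfinite(sensitivity) and precision + sensitivity > 0:
            f_score = 2.0 * precision * sensitivity / (precision + sensitivity)
        elif np.isfinite(precision) and np.isfinite(sensitivity):
            f_score = 0.0
        else:
            f_score = np.nan
            undefined.append((name, "f_score"))
        if tp + fn == 0:
            undefined.append((name, "sensitivity"))
        rows[name] = {
            "accuracy": accuracy,
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "f_score": f_score,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    macro = table.mean(axis=0, skipna=True)
    return ClassMetrics(table=table, macro=macro, undefined=tuple(undefined))


def macro_average(metrics: ClassMetrics) -> pd.Series:
    """Unweighted mean of each metric across classes (NaN entries excluded)."""
    return metrics.table.mean(axis=0, skipna=True)


def classification_error_rate(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Micro error percentage, ``100 x misclassified / total`` — the fitness
    minimized by the hyperparameter search."""
    true_labels = np.asarray(list(true_labels))
    predicted_labels = np.asarray(list(predicted_labels))
    if true_labels.size == 0 or true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    return 100.0 * float(np.mean(true_labels != predicted_labels))


@dataclass
class EvaluationReport:
    """Evaluation of one train/test split: per-phase confusion matrices and
    metric tables, mirroring the benchmark table layout."""

    split_name: str
    phases: dict[str, tuple[ConfusionMatrix, ClassMetrics]] = field(default_factory=dict)

    def add_phase(self, phase: str, matrix: ConfusionMatrix) -> ClassMetrics:
        metrics = per_class_metrics(matrix)
        self.phases[phase] = (matrix, metrics)
        return metrics

    def to_text(self) -> str:
        lines = [f"Split: {self.split_name}", ""]
        for phase, (matrix, metrics) in self.phases.items():
            lines.append(f"== {phase} (n={matrix.total}) ==")
            lines.append("Confusion matrix (rows = true, cols = predicted):")
            lines.append(matrix.to_frame().to_string())
            lines.append("")
            lines.append("Per-class one-vs-rest metrics (%):")
            lines.append(metrics.rounded().to_string())
            lines.append("")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        out: dict = {"split": self.split_name, "phases": {}}
        for phase, (matrix, metrics) in self.phases.items():
            out["phases"][phase] = {
                "n": matrix.total,
                "class_names": list(matrix.class_names),
                "confusion": matrix.counts.tolist(),
                "per_class": {
                    cls: {m: metrics.table.loc[cls, m] for m in METRIC_NAMES}
                    for cls in matrix.class_names
                },
                "macro": {m: float(metrics.macro[m]) for m in METRIC_NAMES},
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
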