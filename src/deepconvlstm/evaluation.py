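"""Class-imbalance-aware scoring of window-level predictions.

Naturalistic activity recordings are dominated by the Null class (time
with no activity of interest), so plain accuracy is uninformative. The
headline metric here is the sample-weighted F1: per-class F1 scores
averaged with weights w_i = n_i / N proportional to each class's share
of the evaluated windows,

    F1 = sum_i 2 * w_i * precision_i * recall_i / (precision_i + recall_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ModelParameters, model_forward
from .preprocessing import WindowBatch, drop_null_windows

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "weighted_f1",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """nc x nc count matrix; rows = actual class, columns = predicted.

    Cell (r, c) is the number of windows whose true class is r and were
    classified as c.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (
            self.counts.ndim != 2
            or self.counts.shape[0] != self.counts.shape[1]
        ):
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-class and weighted metrics."""

    confusion: ConfusionMatrix
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    class_weights: np.ndarray
    weighted_f1: float
    null_mode: str = "included"

    def write(self, confusion_path, metrics_path) -> None:
        """Serialise as two tab-delimited tables plus a summary line."""
        nc = self.confusion.n_classes
        with open(confusion_path, "w") as fh:
            fh.write("actual\\predicted\t" + "\t".join(map(str, range(nc))) + "\n")
            for r in range(nc):
                fh.write(
                    f"{r}\t" + "\t".join(map(str, self.confusion.counts[r])) + "\n"
                )
        with open(metrics_path, "w") as fh:
            fh.write("class\tweight\tprecision\trecall\tf1\n")
            for c in range(nc):
                fh.write(
                    f"{c}\t{self.class_weights[c]:.6f}\t{self.precision[c]:.6f}"
                    f"\t{self.recall[c]:.6f}\t{self.f1[c]:.6f}\n"
                )
            fh.write(
                f"weighted_f1\t{self.weighted_f1:.6f}"
                f"\t(null_mode={self.null_mode})\n"
            )


def confusion_matrix(
    actual: np.ndarray, predicted: np.ndarray, nc: int
) -> ConfusionMatrix:
    """Tally actual-vs-predicted counts over nc classes."""
    actual = np.asarray(actual, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.size and (arr.min() < 0 or arr.max() >= nc):
            raise ValueError(f"{name} labels outside [0, {nc})")
    counts = np.zeros((nc, nc), dtype=np.int64)
    np.add.at(counts, (actual, predicted), 1)
    return ConfusionMatrix(counts=counts)


def _per_class_metrics(cm: ConfusionMatrix):
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    weights = counts.sum(axis=1) / counts.sum()
    return precision, recall, f1, weights


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Sample-weighted F1 over the classes of a confusion matrix.

    Weights are the actual class proportions n_i / N. A class with an
    undefined precision or recall (empty row or column) contributes a
    per-class F1 of 0, keeping the sum defined under extreme imbalance.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    _, _, f1, weights = _per_class_metrics(cm)
    return float((weights * f1).sum())


def evaluate(
    model: ModelParameters,
    windows: WindowBatch,
    null_mode: str = "included",
) -> EvaluationReport:
    """Score a model on a window batch.

    The predicted class of each window is the argmax of the model's
    output distribution (ties break to the lowest class index). With
    ``null_mode="excluded"``, Null-labelled windows are removed and the
    remaining labels shifted to the model's Null-free class set — use
    this with a model trained on the activity classes only.
    """
    if null_mode not in ("included", "excluded"):
        raise ValueError("null_mode must be 'included' or 'excluded'")
    if null_mode == "excluded":
        windows = drop_null_windows(windows)
    nc = model.spec.n_classes
    if windows.labels.size and windows.labels.max() >= nc:
        raise ValueError(
            f"batch labels exceed the model's {nc} classes "
            f"(null_mode={null_mode})"
        )
    probs = model_forward(windows.sequences, model)
    predicted = probs.argmax(axis=1)
    cm = confusion_matrix(windows.labels, predicted, nc)
    precision, recall, f1, weights = _per_class_metrics(cm)
    return EvaluationReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        class_weights=weights,
        weighted_f1=float((weights * f1).sum()),
        null_mode=null_mode,
    )
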