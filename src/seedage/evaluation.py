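"""Confusion-matrix based classification metrics.

Multiclass performance is summarized by an l-by-l confusion matrix (rows =
true class, columns = predicted class) and four derived scores: per-class
averaged accuracy, and precision / recall / F-beta under micro, macro and
weighted averaging.  For single-label problems micro precision, micro recall
and overall accuracy coincide (every false positive is some other class's
false negative), so all three averaging modes are always reported side by
side rather than guessing which one a given publication used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "accuracy_avg",
    "precision_recall_f1",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of (true, predicted) label pairs for an l-class problem."""

    counts: np.ndarray  # (l, l) non-negative ints; rows true, cols predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 classes")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-class (tp, fp, fn, tn); tp+fp+fn+tn == total for every class."""
        c = self.counts
        tp = np.diag(c).astype(np.int64)
        fp = c.sum(axis=0) - tp
        fn = c.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Tally an ``n_classes``-way confusion matrix from integer labels."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        bad = np.flatnonzero((y < 0) | (y >= n_classes))
        if bad.size:
            raise ValueError(
                f"{name}[{bad[0]}] = {y[bad[0]]} outside [0, {n_classes})"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy_avg(cm: ConfusionMatrix) -> float:
    """Average over classes of (tp_i + tn_i) / (tp_i + fp_i + fn_i + tn_i)."""
    tp, fp, fn, tn = cm.per_class()
    denom = tp + fp + fn + tn
    return float(np.mean((tp + tn) / denom))


def _prf(tp: float, fp: float, fn: float, beta: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    b2 = beta * beta
    denom = b2 * precision + recall
    f = (b2 + 1) * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus precision/recall/F-beta for one averaging mode."""

    accuracy_avg: float
    precision: float
    recall: float
    f_score: float
    beta: float = 1.0
    averaging_mode: str = "micro"
    zero_division_flagged: bool = field(default=False, compare=False)


def precision_recall_f1(
    cm: ConfusionMatrix, beta: float = 1.0, mode: str = "micro"
) -> MetricsReport:
    """Precision, recall and F-beta under the requested averaging mode.

    micro pools tp/fp/fn over classes before forming the ratios; macro
    averages the per-class ratios; weighted averages them with true-class
    support weights.  A zero denominator yields 0 and sets the flag.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    tp, fp, fn, _ = cm.per_class()
    flagged = False
    if mode == "micro":
        precision, recall, f = _prf(tp.sum(), fp.sum(), fn.sum(), beta)
        flagged = (tp.sum() + fp.sum() == 0) or (tp.sum() + fn.sum() == 0)
    elif mode in ("macro", "weighted"):
        per = np.array([_prf(*pc, beta) for pc in zip(tp, fp, fn)])
        flagged = bool(((tp + fp) == 0).any() or ((tp + fn) == 0).any())
        if mode == "macro":
            precision, recall, f = per.mean(axis=0)
        else:
            support = tp + fn
            if support.sum() == 0:
                raise ValueError("empty confusion matrix")
            w = support / support.sum()
            precision, recall, f = (per * w[:, None]).sum(axis=0)
    else:
        raise ValueError(f"unknown averaging mode: {mode!r}")
    return MetricsReport(
        accuracy_avg=accuracy_avg(cm),
        precision=float(precision),
        recall=float(recall),
        f_score=float(f),
        beta=beta,
        averaging_mode=mode,
        zero_division_flagged=flagged,
    )


def metrics_report(
    cm: ConfusionMatrix, class_names=None, beta: float = 1.0
) -> dict:
    """All three averaging modes as a JSON-serializable dict."""
    if class_names is None:
        class_names = list(range(cm.n_classes))
    out = {
        "classes": list(class_names),
        "confusion_matrix": cm.counts.tolist(),
        "accuracy_avg": accuracy_avg(cm),
        "beta": beta,
    }
    for mode in ("micro", "macro", "weighted"):
        rep = precision_recall_f1(cm, beta=beta, mode=mode)
        out[mode] = {
            "precision": rep.precision,
            "recall": rep.recall,
            "f_score": rep.f_score,
        }
    return out


def save_metrics_json(cm: ConfusionMatrix, path, class_names=None, beta: float = 1.0):
    with open(path, "w") as fh:
        json.dump(metrics_report(cm, class_names, beta), fh, indent=2)


def save_confusion_csv(cm: ConfusionMatrix, path, class_names=None) -> None:
    """Confusion matrix as CSV with class-name headers (rows = true class)."""
    import pandas as pd

    if class_names is None:
        class_names = list(range(cm.n_classes))
    df = pd.DataFrame(cm.counts, index=class_names, columns=class_names)
    df.to_csv(path, index_label="true\\pred")
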