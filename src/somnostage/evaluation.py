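"""Classification reports and per-stage feature-variability analytics.

Per-class precision, recall and F1 are computed from the confusion
matrix (rows = true stage, columns = predicted stage), together with
macro (unweighted) and support-weighted averages and overall accuracy.
An aggregation audit recomputes the averages from printed per-class
values — useful for checking published tables, since accuracy must equal
the support-weighted mean of the recalls.  The variability analysis
summarises, per stage, the absolute coefficient of variation of every
feature across that stage's 5 s windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassReport",
    "StageVariability",
    "confusion_matrix",
    "classification_report",
    "aggregate_from_per_class",
    "cv_by_stage",
]


@dataclass
class ConfusionMatrix:
    """k×k count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be k×k for k classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def normalized(self) -> np.ndarray:
        """Row-normalised matrix; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.classes)


@dataclass
class ClassReport:
    """Per-class and aggregate classification metrics."""

    classes: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    accuracy: float = 0.0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": {
                c: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.support[i]),
                }
                for i, c in enumerate(self.classes)
            },
            "macro": self.macro,
            "weighted": self.weighted,
            "accuracy": self.accuracy,
            "total_support": int(self.support.sum()),
            "flags": self.flags,
        }

    def to_text(self, decimals: int = 3) -> str:
        """Render like a standard classification report (3-decimal display)."""
        w = max(len(c) for c in self.classes + ["weighted avg"])
        head = f"{'':{w}}  precision  recall  f1-score  support"
        rows = [head]
        for i, c in enumerate(self.classes):
            rows.append(
                f"{c:{w}}  {self.precision[i]:9.{decimals}f}"
                f"  {self.recall[i]:6.{decimals}f}"
                f"  {self.f1[i]:8.{decimals}f}  {self.support[i]:7d}"
            )
        tot = int(self.support.sum())
        rows.append(
            f"{'macro avg':{w}}  {self.macro['precision']:9.{decimals}f}"
            f"  {self.macro['recall']:6.{decimals}f}"
            f"  {self.macro['f1']:8.{decimals}f}  {tot:7d}"
        )
        rows.append(
            f"{'weighted avg':{w}}  {self.weighted['precision']:9.{decimals}f}"
            f"  {self.weighted['recall']:6.{decimals}f}"
            f"  {self.weighted['f1']:8.{decimals}f}  {tot:7d}"
        )
        rows.append(f"{'accuracy':{w}}  {self.accuracy:9.{decimals}f}"
                    f"  {'':6}  {'':8}  {tot:7d}")
        return "\n".join(rows)


@dataclass
class StageVariability:
    """Absolute-CV summary per stage: median, mean and SD across features."""

    stats: dict            # stage -> {median_cv, mean_cv, sd_cv, n_features}
    excluded: dict         # stage -> number of zero-mean features dropped

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.stats).T


def confusion_matrix(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Count matrix over the given (or observed, sorted) class list."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def classification_report(cm: ConfusionMatrix) -> ClassReport:
    """Precision/recall/F1 per class plus macro, weighted and accuracy.

    Zero-prediction or zero-support classes yield flagged zeros rather
    than exceptions, so audits of external reports never abort.
    """
    counts = cm.counts.astype(float)
    k = counts.shape[0]
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    flags = []
    precision = np.zeros(k)
    recall = np.zeros(k)
    for i in range(k):
        if col[i] > 0:
            precision[i] = tp[i] / col[i]
        else:
            flags.append(f"no predictions for class {cm.classes[i]!r}")
        if row[i] > 0:
            recall[i] = tp[i] / row[i]
        else:
            flags.append(f"zero support for class {cm.classes[i]!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    support = row.astype(int)
    total = support.sum()
    macro = {
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }
    weighted = {
        "precision": float((precision * support).sum() / total),
        "recall": float((recall * support).sum() / total),
        "f1": float((f1 * support).sum() / total),
    }
    accuracy = float(tp.sum() / total)
    return ClassReport(
        classes=list(cm.classes), precision=precision, recall=recall,
        f1=f1, support=support, macro=macro, weighted=weighted,
        accuracy=accuracy, flags=flags,
    )


def aggregate_from_per_class(precision, recall, f1, supports) -> dict:
    """Recompute macro/weighted averages and accuracy from per-class values.

    The accuracy identity — support-weighted mean recall — lets printed
    tables be audited without the underlying confusion matrix.
    """
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if not (precision.size == recall.size == f1.size == supports.size):
        raise ValueError("per-class vectors must share one length")
    total = supports.sum()
    return {
        "macro": {
            "precision": float(precision.mean()),
            "recall": float(recall.mean()),
            "f1": float(f1.mean()),
        },
        "weighted": {
            "precision": float((precision * supports).sum() / total),
            "recall": float((recall * supports).sum() / total),
            "f1": float((f1 * supports).sum() / total),
        },
        "accuracy": float((recall * supports).sum() / total),
    }


def cv_by_stage(F, labels, feature_names=None) -> StageVariability:
    """Absolute coefficient of variation of each feature, per stage.

    For stage s and feature f, CV = |sd/mean| × 100 over the 5 s windows
    labelled s (sample sd, n−1).  Per stage, the median, mean and SD of
    the CVs across features are reported; zero-mean features are
    excluded (their CV is undefined) with the exclusion count recorded.
    Stages with fewer than two windows are skipped with a warning.
    """
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    stats, excluded = {}, {}
    for s in np.unique(labels):
        rows = F[labels == s]
        if rows.shape[0] < 2:
            warnings.warn(f"stage {s!r} has fewer than 2 windows; skipped",
                          stacklevel=2)
            continue
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=1)
        nonzero = mean != 0
        cvs = np.abs(sd[nonzero] / mean[nonzero]) * 100.0
        stats[str(s)] = {
            "median_cv": float(np.median(cvs)),
            "mean_cv": float(np.mean(cvs)),
            "sd_cv": float(np.std(cvs, ddof=1)) if cvs.size > 1 else 0.0,
            "n_features": int(cvs.size),
        }
        excluded[str(s)] = int(np.count_nonzero(~nonzero))
    return StageVariability(stats=stats, excluded=excluded)
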