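"""Pixel confusion matrices and the segmentation metric suite.

Every metric is derived from a K x K confusion matrix of pixel counts (rows =
true class, columns = predicted class): per-class TP is the diagonal, FP the
column sum minus the diagonal, FN the row sum minus the diagonal.  PA is the
overall pixel accuracy trace/total; per-class pixel accuracy equals recall, and
MPA averages it over classes; IoU_c = TP/(TP+FP+FN) and mIoU averages it; F1 is
the harmonic mean of precision and recall.  Classes absent from both the
prediction and the truth (TP+FP+FN = 0) are undefined and are excluded from the
MPA and mIoU means rather than counted as 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "normalize_rows",
    "metrics_from_confusion",
    "evaluate_segmentation",
]

DEFAULT_CLASS_NAMES = ("BG", "NL", "HL", "L")


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int64, rows = true, cols = predicted
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion counts must be a square matrix")
        if counts.shape[0] != len(self.class_names):
            raise ValueError("class_names length must match the matrix size")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts).astype(np.int64)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_names != other.class_names:
            raise ValueError("cannot add confusion matrices with different classes")
        return ConfusionMatrix(self.counts + other.counts, self.class_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass(frozen=True)
class MetricsReport:
    """All metrics in [0, 1]; per-class entries are NaN where undefined."""

    pa: float
    mpa: float
    iou: np.ndarray
    miou: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    class_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "PA": self.pa,
            "MPA": self.mpa,
            "mIoU": self.miou,
            "IoU": {n: float(v) for n, v in zip(self.class_names, self.iou)},
            "precision": {n: float(v) for n, v in zip(self.class_names, self.precision)},
            "recall": {n: float(v) for n, v in zip(self.class_names, self.recall)},
            "F1": {n: float(v) for n, v in zip(self.class_names, self.f1)},
        }


def confusion(
    pred: np.ndarray,
    true: np.ndarray,
    n_classes: int,
    class_names: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Tally counts[i, j] = number of pixels with true class i predicted as j."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same number of pixels")
    for name, arr in (("pred", pred), ("true", true)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes - 1}]")
    counts = np.bincount(
        true.astype(np.int64) * n_classes + pred.astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    if class_names is None:
        class_names = (
            DEFAULT_CLASS_NAMES
            if n_classes == len(DEFAULT_CLASS_NAMES)
            else tuple(f"class{i}" for i in range(n_classes))
        )
    return ConfusionMatrix(counts, tuple(class_names))


def normalize_rows(cm: ConfusionMatrix) -> np.ndarray:
    """Row-normalized matrix; each nonzero row sums to 1, diagonal = recall.

    Rows with no true pixels are emitted as zeros with a warning.
    """
    counts = cm.counts.astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    zero_rows = row_sums[:, 0] == 0
    if np.any(zero_rows):
        names = [cm.class_names[i] for i in np.flatnonzero(zero_rows)]
        warnings.warn(f"no true pixels for classes {names}; emitting zero rows")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 0.0)
    return out


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    tp = cm.tp().astype(float)
    fp = cm.fp().astype(float)
    fn = cm.fn().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        iou = np.where(tp + fp + fn > 0, tp / (tp + fp + fn), np.nan)
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), np.nan)
    pa = float(tp.sum() / cm.total)
    mpa = float(np.nanmean(recall)) if np.any(np.isfinite(recall)) else float("nan")
    miou = float(np.nanmean(iou)) if np.any(np.isfinite(iou)) else float("nan")
    return MetricsReport(
        pa=pa,
        mpa=mpa,
        iou=iou,
        miou=miou,
        precision=precision,
        recall=recall,
        f1=f1,
        class_names=cm.class_names,
    )


def evaluate_segmentation(
    pred: np.ndarray, true: np.ndarray, n_classes: int = 4
) -> MetricsReport:
    """Convenience wrapper: confusion + metrics in one call."""
    return metrics_from_confusion(confusion(pred, true, n_classes))
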