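"""Segmentation and counting evaluation metrics, fold summaries, paired t-test.

Segmentation quality is scored from the pixel confusion matrix in one-vs-rest
form: per-class precision TP/(TP+FP), recall TP/(TP+FN) and IoU
TP/(TP+FP+FN); mPA averages the per-class pixel accuracies and mIoU the
per-class IoUs over all classes (background included).  A class absent from
both masks has an undefined score (NaN) and is excluded from the means rather
than silently counted as zero.

Counting quality compares predicted whole-spike counts y_i with manual truth
x_i: per-sample relative error p_i = |x_i - y_i| / x_i * 100, MAE, RMSE, MRE
(the mean of the p_i, already a percentage), and the coefficient of
determination R^2 = 1 - sum (x_i - y_i)^2 / sum (x_i - x_bar)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "SegScores",
    "CountSeries",
    "CountScores",
    "PairedTestResult",
    "DegenerateInputError",
    "confusion",
    "precision",
    "recall",
    "iou",
    "mean_scores",
    "count_metrics",
    "paired_t_test",
    "summarize_folds",
]


class DegenerateInputError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest pixel counts for k categories.

    ``tn`` is carried for completeness; none of the reported scores uses it.
    """

    k: int
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """P_k: fraction of each class's true pixels that were predicted as it."""
        return _safe_div(self.tp, self.tp + self.fn)


@dataclass
class SegScores:
    precision: np.ndarray
    recall: np.ndarray
    iou: np.ndarray
    mpa: float
    miou: float


@dataclass
class CountSeries:
    """True counts x and predicted counts y for n samples."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or self.x.size == 0:
            raise ValueError("x and y must be equal-length non-empty 1-D series")
        if np.any(self.x <= 0):
            raise ValueError("true counts must be positive (relative error divides by x)")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class CountScores:
    p: np.ndarray  # per-sample relative error, percent
    rmse: float
    mae: float
    mre: float  # percent
    r2: float  # NaN when undefined (constant truth)


@dataclass
class PairedTestResult:
    t: float
    p_value: float
    n: int


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def confusion(pred: np.ndarray, truth: np.ndarray, k: int = 2) -> ConfusionMatrix:
    """Pixel confusion counts between predicted and true label masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.min() < 0 or pred.max() >= k or truth.min() < 0 or truth.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    m = np.bincount(
        truth.ravel().astype(np.int64) * k + pred.ravel().astype(np.int64),
        minlength=k * k,
    ).reshape(k, k)
    tp = np.diag(m).astype(np.int64)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return ConfusionMatrix(k=k, tp=tp, fp=fp, fn=fn, tn=tn)


def precision(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class TP / (TP + FP); NaN where the class is never predicted."""
    return _safe_div(cm.tp, cm.tp + cm.fp)


def recall(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class TP / (TP + FN); NaN where the class has no true pixels."""
    return _safe_div(cm.tp, cm.tp + cm.fn)


def iou(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class TP / (TP + FP + FN); NaN where the class is absent from both."""
    return _safe_div(cm.tp, cm.tp + cm.fp + cm.fn)


def mean_scores(cm: ConfusionMatrix) -> SegScores:
    """Per-class scores plus their means over the defined classes."""
    if cm.k < 2:
        raise ValueError("mean scores need at least 2 categories")
    prec, rec, jac = precision(cm), recall(cm), iou(cm)
    with np.errstate(invalid="ignore"):
        mpa = float(np.nanmean(cm.per_class_accuracy))
        miou = float(np.nanmean(jac))
    return SegScores(precision=prec, recall=rec, iou=jac, mpa=mpa, miou=miou)


def count_metrics(series: CountSeries) -> CountScores:
    """Counting-accuracy scores; R^2 is NaN when the truth is constant."""
    x, y = series.x, series.y
    err = x - y
    p = np.abs(err) / x * 100.0
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mre = float(np.mean(p))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    return CountScores(p=p, rmse=rmse, mae=mae, mre=mre, r2=r2)


def paired_t_test(a, b) -> PairedTestResult:
    """Two-sided paired t-test on per-fold values, n-1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("paired differences have zero variance")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t=t, p_value=p, n=n)


def summarize_folds(values) -> tuple[float, float | None]:
    """Mean and sample standard deviation (ddof=1); std is None for one value."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("need a non-empty 1-D sequence of fold values")
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if values.size > 1 else None
    return mean, std
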