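"""Evaluation suite: confusion-matrix metrics, cross-validation, ROC/AUC,
plus the PSNR and Dice instruments used by the image stages.

Ten confusion-matrix metrics are computed from (Tp, Tn, Fp, Fn) with
malignant (label 1) as the positive class by default.  Ratios with a zero
denominator are reported as NaN with a warning and excluded from fold
averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

#: PSNR reported for identical images (MSE = 0), instead of +inf
PSNR_CAP_DB = 100.0

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity",
                "npv", "fpr", "fdr", "fnr", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Counts with ``positive_label`` (malignant) as the positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    labels = set(np.unique(yt)) | set(np.unique(yp))
    if len(labels) > 2:
        raise ValueError(f"labels must be binary, got {sorted(labels)}")
    tpos = yt == positive_label
    ppos = yp == positive_label
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """All ten confusion-matrix metrics (accuracy … MCC)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        if not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("f1 undefined (precision + recall = 0); reporting NaN",
                          RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * recall * precision / (recall + precision)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warnings.warn("mcc undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=2)
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        accuracy=(tp + tn) / counts.total,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_ratio(tn, tn + fp, "specificity"),
        npv=_ratio(tn, tn + fn, "npv"),
        fpr=_ratio(fp, fp + tn, "fpr"),
        fdr=_ratio(fp, fp + tp, "fdr"),
        fnr=_ratio(fn, fn + tp, "fnr"),
        mcc=mcc,
    )


def kfold_evaluate(X, y, k: int, pipeline_fn: Callable, seed: int = 0,
                   positive_label=1) -> dict:
    """Stratified k-fold evaluation; every sample is tested exactly once.

    ``pipeline_fn(X_train, y_train, X_test) -> y_pred`` trains a fresh model
    per fold.  Returns per-fold reports, their unweighted mean (NaN entries
    excluded, with a count of defined folds per metric), and the test-fold
    index partition.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    fold_indices: list[np.ndarray] = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold lost one of the classes")
        y_pred = pipeline_fn(X[tr], y[tr], X[te])
        fold_reports.append(
            classification_metrics(confusion(y[te], y_pred, positive_label))
        )
        fold_indices.append(te)
    avg, n_defined = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in fold_reports])
        defined = vals[~np.isnan(vals)]
        n_defined[name] = int(defined.size)
        avg[name] = float(defined.mean()) if defined.size else float("nan")
    return {
        "folds": fold_reports,
        "average": avg,
        "n_defined": n_defined,
        "test_indices": fold_indices,
    }


def roc_auc(scores, y_true, positive_label=1) -> tuple[np.ndarray, float]:
    """ROC points and AUC via the rank (Mann–Whitney) formulation, ties averaged.

    Higher scores must indicate the positive class.  Returns an array of
    (fpr, tpr) points (one per distinct threshold, endpoints included) and
    the AUC.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_true) == positive_label
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    distinct = np.r_[np.nonzero(np.diff(ss))[0], ss.size - 1]
    tp_cum = np.cumsum(ys)[distinct]
    fp_cum = np.cumsum(~ys)[distinct]
    curve = np.column_stack([
        np.r_[0.0, fp_cum / n_neg],
        np.r_[0.0, tp_cum / n_pos],
    ])
    return curve, float(auc)


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB with MAX = 255; capped for identical inputs."""
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError("shape mismatch")
    mse = np.mean((ref - tst) ** 2)
    if mse == 0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(255.0 ** 2 / mse))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks count as identical (1)."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.sum(a & b) / denom
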