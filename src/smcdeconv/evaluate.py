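"""Evaluation metrics: proportion recovery and fold-change DE detection.

Proportion recovery is scored by the mean absolute difference (MAD) and the
Pearson correlation between true and estimated proportion matrices.  DE
detection between a pair of cell types uses the fold-change rule: gene i is
truly differentially expressed with type r upregulated against type u iff
``FC_i = max(x_ir, x_iu)/min(x_ir, x_iu) > 2`` and ``x_ir > x_iu``.
Predictions sweep the fold-change threshold from 1 to 5 in steps of 0.25 and
are summarized by ROC curves and the trapezoidal AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "mad",
    "pearson_r",
    "fold_change",
    "de_truth_labels",
    "confusion_counts",
    "roc_curve",
    "auroc",
    "DEFAULT_THRESHOLDS",
]

# 1, 1.25, ..., 5 — seventeen fold-change thresholds
DEFAULT_THRESHOLDS = np.round(np.arange(1.0, 5.0 + 0.25 / 2, 0.25), 10)


@dataclass(frozen=True)
class ROCResult:
    """ROC over the fold-change threshold sweep for one (up, ref) pair."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    pair: tuple[int, int]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(np.diff(self.tpr) > 1e-12) or np.any(np.diff(self.fpr) > 1e-12):
            raise ValueError("TPR/FPR must be non-increasing in the threshold")
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("AUROC must lie in [0, 1]")


def mad(M_true: np.ndarray, M_est: np.ndarray) -> float:
    """Mean absolute difference over all entries (labels already aligned)."""
    M_true = np.asarray(M_true, dtype=float)
    M_est = np.asarray(M_est, dtype=float)
    if M_true.shape != M_est.shape:
        raise ValueError(f"shape mismatch: {M_true.shape} vs {M_est.shape}")
    return float(np.mean(np.abs(M_true - M_est)))


def pearson_r(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation over the flattened entries of two equal-shape arrays."""
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    if A.shape != B.shape:
        raise ValueError("arrays must have equal shapes")
    if A.size < 2:
        raise ValueError("need at least two entries")
    if np.std(A) == 0 or np.std(B) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(A, B).statistic)


def fold_change(x_r: float, x_u: float) -> float:
    """Symmetric fold change max(x_r, x_u) / min(x_r, x_u), >= 1."""
    if x_r <= 0 or x_u <= 0:
        raise ValueError("fold change requires strictly positive expressions")
    hi, lo = (x_r, x_u) if x_r >= x_u else (x_u, x_r)
    return hi / lo


def _fc_and_direction(X: np.ndarray, r: int, u: int) -> tuple[np.ndarray, np.ndarray]:
    xr, xu = X[:, r], X[:, u]
    if np.any(xr <= 0) or np.any(xu <= 0):
        raise ValueError("fold change requires strictly positive expressions")
    fc = np.maximum(xr, xu) / np.minimum(xr, xu)
    return fc, xr > xu


def de_truth_labels(X_true: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
    """True DE labels for 'r upregulated vs u': FC > 2 (strict) and x_ir > x_iu."""
    r, u = pair
    fc, up = _fc_and_direction(np.asarray(X_true, dtype=float), r, u)
    return (fc > 2.0) & up


def confusion_counts(
    pred_positive: np.ndarray, truth_positive: np.ndarray
) -> tuple[int, int, int, int]:
    """Standard (TP, FP, FN, TN) counts from boolean vectors."""
    pred = np.asarray(pred_positive, dtype=bool)
    truth = np.asarray(truth_positive, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return tp, fp, fn, tn


def auroc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under the ROC, corners (0,0) and (1,1) appended."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    d = np.diff(fpr)
    if np.any(d > 0) and np.any(d < 0):
        warnings.warn("ROC points not monotone in FPR; sorting before integration",
                      UserWarning, stacklevel=2)
    f = np.concatenate([[0.0], np.sort(fpr), [1.0]])
    t = np.concatenate([[0.0], np.sort(tpr), [1.0]])
    return float(np.trapezoid(t, f))


def roc_curve(
    X_hat: np.ndarray,
    truth_labels: np.ndarray,
    pair: tuple[int, int],
    thresholds: np.ndarray | None = None,
) -> ROCResult:
    """ROC over the fold-change threshold sweep.

    At threshold c a gene is predicted DE (r upregulated vs u) iff its
    estimated fold change strictly exceeds c and the estimated direction
    matches.  Genes truly DE in the opposite direction count as negatives.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    truth = np.asarray(truth_labels, dtype=bool)
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == truth.size:
        raise ValueError("ROC undefined: truth needs both positives and negatives")
    r, u = pair
    fc, up = _fc_and_direction(np.asarray(X_hat, dtype=float), r, u)
    tpr_list, fpr_list = [], []
    for c in thresholds:
        pred = (fc > c) & up
        tp, fp, fn, tn = confusion_counts(pred, truth)
        tpr_list.append(tp / (tp + fn))
        fpr_list.append(fp / (fp + tn))
    tpr = np.asarray(tpr_list)
    fpr = np.asarray(fpr_list)
    return ROCResult(
        thresholds=np.asarray(thresholds, dtype=float),
        tpr=tpr,
        fpr=fpr,
        auroc=auroc(fpr, tpr),
        pair=(r, u),
    )
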