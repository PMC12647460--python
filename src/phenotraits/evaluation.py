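"""Instance-segmentation and trait-agreement evaluation.

Implements the pipeline's metric suite: IoU-based instance matching with
TP/FP/FN bookkeeping, precision / recall / F1, the count discrepancy DiC
``|#L_pred - #L_truth|``, the mean absolute percentage error (MAPE, in %)
between automated and manual measurements, and the coefficient of
determination R^2 of the ordinary least-squares fit of manual values
(response) on automated values (predictor).

Matching is greedy in descending IoU with deterministic tie-breaks (lower
predicted label first, then lower truth label); each predicted and each
truth instance participates in at most one pair. The default IoU threshold
for declaring a true positive is 0.5 and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult",
    "AgreementReport",
    "iou_matrix",
    "match_instances",
    "precision_recall_f1",
    "dic",
    "mean_dic",
    "mape",
    "r_squared",
]


@dataclass
class MatchResult:
    """Bipartite assignment of predicted to ground-truth instances."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0  # fixed 0 for instance tasks; kept for formula completeness
    n_pred: int = 0
    n_truth: int = 0


@dataclass
class AgreementReport:
    """Agreement between automated and manual measurements of one trait."""

    r_squared: float
    mape_percent: float
    slope: float
    intercept: float
    n: int


def iou_matrix(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pairwise IoU of predicted vs truth instances.

    Returns an ``(n_pred, n_truth)`` array where entry ``(p-1, t-1)`` is the
    pixel-set IoU of predicted label ``p`` and truth label ``t``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth maps have different dimensions")
    n_pred = int(pred.max())
    n_truth = int(truth.max())
    if n_pred == 0 or n_truth == 0:
        return np.zeros((n_pred, n_truth))
    joint = np.bincount(
        (pred.ravel() * (n_truth + 1) + truth.ravel()),
        minlength=(n_pred + 1) * (n_truth + 1),
    ).reshape(n_pred + 1, n_truth + 1)
    inter = joint[1:, 1:].astype(np.float64)
    a_pred = np.bincount(pred.ravel(), minlength=n_pred + 1)[1:].astype(np.float64)
    a_truth = np.bincount(truth.ravel(), minlength=n_truth + 1)[1:].astype(np.float64)
    union = a_pred[:, None] + a_truth[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_instances(
    pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """Greedily match predicted to truth instances at the given IoU threshold."""
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    iou = iou_matrix(pred, truth)
    n_pred, n_truth = iou.shape
    cand = [
        (float(iou[p, t]), p + 1, t + 1)
        for p in range(n_pred)
        for t in range(n_truth)
        if iou[p, t] >= iou_threshold
    ]
    # descending IoU, then lower predicted label, then lower truth label
    cand.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for v, p, t in cand:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        pairs.append((p, t, v))
    tp = len(pairs)
    return MatchResult(
        pairs=pairs,
        TP=tp,
        FP=n_pred - tp,
        FN=n_truth - tp,
        TN=0,
        n_pred=n_pred,
        n_truth=n_truth,
    )


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN)."""
    nan = float("nan")
    if m.TP + m.FP > 0:
        precision = m.TP / (m.TP + m.FP)
    else:
        warnings.warn("precision undefined: no predicted instances")
        precision = nan
    if m.TP + m.FN > 0:
        recall = m.TP / (m.TP + m.FN)
    else:
        warnings.warn("recall undefined: no truth instances")
        recall = nan
    if 2 * m.TP + m.FP + m.FN > 0:
        f1 = 2 * m.TP / (2 * m.TP + m.FP + m.FN)
    else:
        warnings.warn("F1 undefined: empty prediction and truth")
        f1 = nan
    return precision, recall, f1


def dic(pred_count: int, truth_count: int) -> int:
    """Difference in count: absolute discrepancy |#L_pred - #L_truth|."""
    if pred_count < 0 or truth_count < 0:
        raise ValueError("counts must be non-negative")
    return abs(int(pred_count) - int(truth_count))


def mean_dic(pred_counts, truth_counts) -> float:
    """Batch mean of per-image DiC values."""
    pred_counts = list(pred_counts)
    truth_counts = list(truth_counts)
    if len(pred_counts) != len(truth_counts) or not pred_counts:
        raise ValueError("count lists must be non-empty and of equal length")
    return float(np.mean([dic(p, t) for p, t in zip(pred_counts, truth_counts)]))


def mape(auto, manual) -> float:
    """Mean absolute percentage error of automated vs manual values, in %."""
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.size == 0:
        raise ValueError("value lists must be non-empty and of equal length")
    zeros = np.nonzero(manual == 0)[0]
    if zeros.size:
        raise ValueError(f"manual value is zero at index {int(zeros[0])}")
    return float(np.mean(np.abs(auto - manual) / np.abs(manual)) * 100.0)


def r_squared(auto, manual) -> AgreementReport:
    """OLS of manual (response) on automated (predictor) with R^2 and MAPE.

    R^2 = 1 - SS_res/SS_tot; a constant manual series gives R^2 = 0, and a
    zero-variance predictor gives NaN. MAPE is included when defined (no
    zero manual values), else NaN.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.size < 2:
        raise ValueError("need at least two paired values")
    n = auto.size
    nan = float("nan")
    sxx = float(np.sum((auto - auto.mean()) ** 2))
    if sxx == 0:
        return AgreementReport(nan, nan, nan, nan, n)
    sxy = float(np.sum((auto - auto.mean()) * (manual - manual.mean())))
    slope = sxy / sxx
    intercept = float(manual.mean() - slope * auto.mean())
    ss_tot = float(np.sum((manual - manual.mean()) ** 2))
    ss_res = float(np.sum((manual - slope * auto - intercept) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    try:
        m = mape(auto, manual)
    except ValueError:
        m = nan
    return AgreementReport(r2, m, slope, intercept, n)
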