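"""Evaluation metrics: confusion-matrix statistics and cluster matching.

Classification metrics follow the per-class confusion-matrix
formulation: with M[i, j] the count of class-i instances classified as
class j and, for class l,

    p_l = M[l, l]                  (true positives of class l)
    q_l = sum of M[i, j], i != l, j != l
    r_l = sum of M[i, l], i != l   (false positives into l)
    s_l = sum of M[l, j], j != l   (misses out of l)

precision PR_l = p_l / (p_l + r_l), sensitivity SE_l = p_l / (p_l + s_l)
and MCC_l = (p_l q_l - r_l s_l) / sqrt((p_l+r_l)(p_l+s_l)(q_l+r_l)(q_l+s_l));
for two classes both per-class MCCs equal the textbook binary MCC, which
is also reported as the overall MCC.  Cells with a zero denominator are
reported as NaN (undefined), never as 0.

Cluster matching uses the Jaccard index: a predicted cluster matches a
reference cluster when |P ∩ C| / |P ∪ C| >= xi (default 0.5); precision
is the matched fraction of predictions, recall the matched fraction of
references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

#: Class order used throughout: index 0 = positive (+1, direct contact),
#: index 1 = negative (-1, indirect).
POSITIVE, NEGATIVE = 0, 1


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> np.ndarray:
    """2x2 matrix M[i, j] = truth class i predicted as class j.

    Inputs use labels +1 / -1; undetermined predictions (0) must be
    filtered out beforehand (see :func:`discard_undetermined`).
    """
    m = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in (+1, -1) or p not in (+1, -1):
            raise ValueError(f"labels must be +1/-1, got truth={t} pred={p}")
        m[POSITIVE if t == 1 else NEGATIVE, POSITIVE if p == 1 else NEGATIVE] += 1
    return m


def discard_undetermined(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[list[int], list[int], float]:
    """Drop pairs with undetermined (0) predictions.

    Returns the filtered labels and the coverage fraction (determined /
    total), reported separately rather than folded into the matrix.
    """
    kept = [(t, p) for t, p in zip(y_true, y_pred) if p != 0]
    coverage = len(kept) / len(y_true) if len(y_true) else math.nan
    return [t for t, _ in kept], [p for _, p in kept], coverage


@dataclass(frozen=True)
class ClassMetrics:
    precision: tuple[float, float]   # per class (positive, negative)
    sensitivity: tuple[float, float]
    mcc: tuple[float, float]
    accuracy: float
    overall_mcc: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def _mcc(p: float, q: float, r: float, s: float) -> float:
    den = math.sqrt((p + r) * (p + s) * (q + r) * (q + s))
    return (p * q - r * s) / den if den != 0 else math.nan


def class_metrics(m: np.ndarray) -> ClassMetrics:
    """Per-class PR/SE/MCC plus overall Acc and MCC from a 2x2 matrix."""
    m = np.asarray(m)
    if m.shape != (2, 2) or (m < 0).any():
        raise ValueError("confusion matrix must be 2x2 with non-negative counts")
    if m.sum() == 0:
        raise ValueError("confusion matrix is empty")
    pr, se, mcc = [], [], []
    for l in (0, 1):
        o = 1 - l
        p_l = float(m[l, l])
        q_l = float(m[o, o])
        r_l = float(m[o, l])
        s_l = float(m[l, o])
        pr.append(_safe_div(p_l, p_l + r_l))
        se.append(_safe_div(p_l, p_l + s_l))
        mcc.append(_mcc(p_l, q_l, r_l, s_l))
    acc = float(np.trace(m)) / float(m.sum())
    # For two classes the per-class MCC formula already *is* the textbook
    # binary MCC and both classes yield the same value, so the overall MCC
    # is reported as that quantity.  (Summing the per-class intermediates
    # before applying the formula would instead collapse to
    # (p - r) / (p + r), which is not an MCC.)
    return ClassMetrics(
        precision=(pr[0], pr[1]),
        sensitivity=(se[0], se[1]),
        mcc=(mcc[0], mcc[1]),
        accuracy=acc,
        overall_mcc=mcc[0],
    )


def f1(precision: float, sensitivity: float) -> float:
    """Harmonic mean of positive-class precision and sensitivity."""
    if math.isnan(precision) or math.isnan(sensitivity):
        return math.nan
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def roc_auc(decision_values: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC-AUC of combined decision values (midrank ties)."""
    labels = np.asarray(labels)
    values = np.asarray(decision_values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("decision values contain NaN (unpredictable pairs)")
    return float(roc_auc_score((labels == 1).astype(int), values))


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B| of two gene sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def cluster_prf(
    predicted: Sequence[Iterable],
    reference: Sequence[Iterable],
    xi: float = 0.5,
) -> tuple[float, float, float]:
    """Cluster-level (precision, recall, F-score) at Jaccard threshold xi.

    precision: fraction of predicted clusters matching >= 1 reference
    cluster at Jaccard >= xi; recall: fraction of reference clusters
    matched by >= 1 prediction; F: their harmonic mean.
    """
    if not 0 < xi <= 1:
        raise ValueError("xi must be in (0, 1]")
    predicted = [set(c) for c in predicted]
    reference = [set(c) for c in reference]
    if not predicted or not reference:
        raise ValueError("predicted and reference cluster lists must be non-empty")
    matched_pred = sum(
        1 for p in predicted if any(jaccard(p, c) >= xi for c in reference)
    )
    matched_ref = sum(
        1 for c in reference if any(jaccard(p, c) >= xi for p in predicted)
    )
    precision = matched_pred / len(predicted)
    recall = matched_ref / len(reference)
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)
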