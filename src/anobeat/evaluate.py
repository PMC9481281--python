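"""Detector evaluation: confusion counts, ACC/Pre/Rec/F1 and rank AUC.

The abnormal class is the positive one.  AUC is the Mann-Whitney rank
statistic on continuous anomaly scores — the probability that a random
abnormal beat outscores a random normal beat, ties credited one half —
which is threshold-free and invariant to monotone rescaling of scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "binarize_labels",
    "confusion",
    "metrics",
    "f1_score",
    "auc",
    "evaluate",
]

_BINARY = ("normal", "abnormal")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    counts: ConfusionCounts
    acc: float
    pre: float | None   # None when the denominator is zero
    rec: float | None
    f1: float | None
    auc: float | None = None


def binarize_labels(class_labels: np.ndarray) -> np.ndarray:
    """Map beat classes to {normal, abnormal}: N is normal, A/L/R/V abnormal."""
    labels = np.asarray(class_labels)
    return np.where(labels == "N", "normal", "abnormal")


def confusion(true_labels: np.ndarray, pred_labels: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with abnormal as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        bad = set(arr.tolist()) - set(_BINARY)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    tpos = t == "abnormal"
    ppos = p == "abnormal"
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def f1_score(pre: float, rec: float) -> float:
    """Harmonic mean of precision and recall."""
    if pre + rec == 0:
        return 0.0
    return 2.0 * pre * rec / (pre + rec)


def metrics(counts: ConfusionCounts) -> tuple[float, float | None,
                                              float | None, float | None]:
    """``(acc, pre, rec, f1)``; undefined ratios are returned as None."""
    if counts.n == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    acc = (counts.tp + counts.tn) / counts.n
    pre = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    f1 = f1_score(pre, rec) if pre is not None and rec is not None else None
    return acc, pre, rec, f1


def auc(scores: np.ndarray, true_labels: np.ndarray) -> float:
    """Rank-based AUC of anomaly scores against binary truth.

    Equals the fraction of (abnormal, normal) pairs where the abnormal beat
    scores higher, ties counting one half (Mann-Whitney U / (n1*n0)).
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(true_labels)
    if s.shape != t.shape:
        raise ValueError("scores and labels differ in length")
    pos = t == "abnormal"
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both normal and abnormal beats")
    ranks = rankdata(s)  # average ranks handle ties as 1/2 credit
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate(true_labels: np.ndarray, pred_labels: np.ndarray,
             scores: np.ndarray | None = None) -> EvalReport:
    """Full report from binary truth, predictions and optional scores."""
    counts = confusion(true_labels, pred_labels)
    acc, pre, rec, f1 = metrics(counts)
    a = auc(scores, true_labels) if scores is not None else None
    return EvalReport(counts, acc, pre, rec, f1, a)
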