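"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, cutoff sweep.

Coding is the positive class throughout.  AUC is computed as the normalized
Mann-Whitney U statistic with midrank handling of ties (a tied
positive/negative pair contributes 0.5), which equals the trapezoidal area
under the ROC curve over all thresholds.  The operating cutoff is chosen by
sweeping candidate thresholds at the midpoints between consecutive unique
scores and keeping the one with the best accuracy (ties go to the smallest
cutoff), mirroring how a default decision threshold is selected against a
labeled testing set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

POSITIVE = "coding"


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


@dataclass
class ConfusionMetrics:
    TP: int
    FP: int
    TN: int
    FN: int
    ACC: float
    Sn: float
    Sp: float
    PPV: float
    NPV: float
    MCC: float
    has_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "ACC": self.ACC, "Sn": self.Sn, "Sp": self.Sp,
            "PPV": self.PPV, "NPV": self.NPV, "MCC": self.MCC,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(predicted: Sequence, truth: Sequence) -> ConfusionMetrics:
    """ACC, Sn, Sp, PPV, NPV and MCC from predicted vs true labels.

    Labels may be strings ("coding"/"noncoding") or 0/1 integers.
    Degenerate ratios (e.g. PPV with no predicted positives) are reported
    as NaN with ``has_undefined`` set and a warning.
    """
    pred = _as_binary(predicted)
    true = _as_binary(truth)
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else math.nan
    undefined = any(math.isnan(v) for v in (sn, sp, ppv, npv, mcc))
    if undefined:
        warnings.warn("confusion table has degenerate margins; some metrics are NaN",
                      stacklevel=2)
    return ConfusionMetrics(tp, fp, tn, fn, acc, sn, sp, ppv, npv, mcc, undefined)


def roc_auc(scores: Sequence[float], truth: Sequence) -> float:
    """AUC via the rank-sum (Mann-Whitney) formula with midranks for ties."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: Sequence[float], truth: Sequence) -> list[tuple[float, float, float]]:
    """(FPR, TPR, threshold) triples over all distinct score thresholds."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    points = [(0.0, 0.0, math.inf)]
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tpr = float(np.sum(pred & (y == 1))) / n_pos
        fpr = float(np.sum(pred & (y == 0))) / n_neg
        points.append((fpr, tpr, float(thr)))
    return points


def best_accuracy_cutoff(
    scores: Sequence[float], truth: Sequence, grid_step: float = 1e-4
) -> tuple[float, float]:
    """Cutoff maximizing accuracy of the rule "coding iff score >= cutoff".

    Candidates are the midpoints between consecutive unique scores plus the
    two half-open extremes (everything coding / everything noncoding).
    Ties go to the smallest cutoff.  ``grid_step`` only rounds the reported
    cutoff, and only when rounding does not change any classification.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    u = np.unique(s)
    candidates = [u[0] / 2.0] if u[0] > 0 else [u[0] - 0.5]
    candidates.extend((u[:-1] + u[1:]) / 2.0)
    candidates.append((u[-1] + 1.0) / 2.0 if u[-1] < 1.0 else u[-1] + 0.5)
    best_cut, best_acc = candidates[0], -1.0
    for c in candidates:
        acc = float(np.mean((s >= c).astype(int) == y))
        if acc > best_acc:
            best_cut, best_acc = float(c), acc
    rounded = round(best_cut / grid_step) * grid_step
    if np.array_equal(s >= rounded, s >= best_cut):
        best_cut = float(rounded)
    return best_cut, best_acc


def write_metrics_tsv(metrics: ConfusionMetrics, path) -> None:
    with open(path, "w") as out:
        d = metrics.as_dict()
        out.write("\t".join(d.keys()) + "\n")
        out.write("\t".join(
            str(v) if isinstance(v, int) else f"{v:.6g}" for v in d.values()
        ) + "\n")


def write_roc_tsv(scores: Sequence[float], truth: Sequence, path) -> None:
    with open(path, "w") as out:
        out.write("fpr\ttpr\tthreshold\n")
        for fpr, tpr, thr in roc_points(scores, truth):
            out.write(f"{fpr:.6g}\t{tpr:.6g}\t{thr:.6g}\n")
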