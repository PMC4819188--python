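"""Binary classification performance indices and ROC/AUC.

Conventions: labels are ±1.  Sensitivity SE = TP/(TP+FN), specificity
SP = TN/(TN+FP), precision PRE = TP/(TP+FP), accuracy ACC = (TP+TN)/n.
Ratios with a zero denominator are reported as None (undefined) rather
than silently as zero, because zeros corrupt averages.  The ROC curve is
built by a threshold sweep over the unique score values (ties cross the
threshold simultaneously) with the (0,0) and (1,1) anchors, and AUC is the
trapezoid-rule area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class EvaluationReport:
    TP: int
    TN: int
    FP: int
    FN: int
    SE: float | None
    SP: float | None
    PRE: float | None
    ACC: float | None
    AUC: float | None = None
    roc_points: list[tuple[float, float]] | None = None

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


def classification_metrics(y: np.ndarray, y_hat: np.ndarray) -> EvaluationReport:
    """Exact confusion counts and the four indices from ±1 labels."""
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=int)
    if y.size != y_hat.size:
        raise ValueError("label vectors differ in length")
    tp = int(((y == 1) & (y_hat == 1)).sum())
    tn = int(((y == -1) & (y_hat == -1)).sum())
    fp = int(((y == -1) & (y_hat == 1)).sum())
    fn = int(((y == 1) & (y_hat == -1)).sum())
    return EvaluationReport(
        TP=tp,
        TN=tn,
        FP=fp,
        FN=fn,
        SE=_ratio(tp, tp + fn, "SE"),
        SP=_ratio(tn, tn + fp, "SP"),
        PRE=_ratio(tp, tp + fp, "PRE"),
        ACC=_ratio(tp + tn, tp + tn + fp + fn, "ACC"),
    )


def roc_auc(y: np.ndarray, scores: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoid AUC."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tp = fp = 0
    points = [(0.0, 0.0)]
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and ss[j] == ss[i]:  # tied scores cross together
            if ys[j] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ts = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ts, xs))
    return points, auc


def evaluate_predictions(
    y: np.ndarray, scores: np.ndarray, threshold: float = 0.0
) -> EvaluationReport:
    """Full report: indices at the given score threshold, plus ROC/AUC."""
    y_hat = np.where(np.asarray(scores) >= threshold, 1, -1)
    rep = classification_metrics(y, y_hat)
    rep.roc_points, rep.AUC = roc_auc(y, scores)
    return rep


def metrics_table_row(name: str, rep: EvaluationReport) -> str:
    """One delimited row in the layout exp/n_pos/n_neg/SE/SP/PRE/ACC/AUC."""
    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.4f}"

    n_pos = rep.TP + rep.FN
    n_neg = rep.TN + rep.FP
    return "\t".join(
        [name, str(n_pos), str(n_neg), fmt(rep.SE), fmt(rep.SP), fmt(rep.PRE),
         fmt(rep.ACC), fmt(rep.AUC)]
    )
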