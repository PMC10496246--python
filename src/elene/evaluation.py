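"""Binary classification metrics: confusion-matrix rates and ROC/AUC.

Rates are reported in percent (two decimals in text reports).  Undefined
ratios (zero denominators) are NaN with an explicit flag, never silently 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .errors import InputError, UndefinedAUCError


@dataclass
class BinaryMetrics:
    TP: int
    FP: int
    FN: int
    TN: int
    accuracy: float       # percent
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: Optional[float] = None
    undefined: tuple[str, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return json.dumps(d, indent=2)

    def report(self) -> str:
        lines = [f"TP={self.TP} FP={self.FP} FN={self.FN} TN={self.TN}"]
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                     "auc"):
            v = getattr(self, name)
            shown = "undefined" if v is None or np.isnan(v) else f"{v:.2f}%"
            lines.append(f"{name:>12}: {shown}")
        return "\n".join(lines)


def _rate(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return 100.0 * num / den


def confusion_metrics(pred, truth,
                      scores=None) -> BinaryMetrics:
    """Standard binary confusion rates (percent) from 0/1 label vectors."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape or pred.size == 0:
        raise InputError("pred and truth must be equal-length, non-empty")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    und: list[str] = []
    m = BinaryMetrics(
        TP=tp, FP=fp, FN=fn, TN=tn,
        accuracy=_rate(tp + tn, tp + tn + fp + fn, "accuracy", und),
        sensitivity=_rate(tp, tp + fn, "sensitivity", und),
        specificity=_rate(tn, tn + fp, "specificity", und),
        ppv=_rate(tp, tp + fp, "ppv", und),
        npv=_rate(tn, tn + fn, "npv", und),
    )
    if scores is not None and len(np.unique(truth)) == 2:
        m.auc = roc_auc(scores, truth)[0]
    m.undefined = tuple(und)
    return m


def roc_auc(scores, truth) -> tuple[float, np.ndarray]:
    """AUC (percent) by the tie-corrected Mann-Whitney rank formula,
    plus the ROC step curve as an array of (FPR, TPR) points."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape:
        raise InputError("scores and truth must be equal-length")
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truth[order]
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and s_sorted[j] == s_sorted[i]:
            tp += int(t_sorted[j] == 1)
            fp += int(t_sorted[j] == 0)
            j += 1
        pts.append((fp / n_neg, tp / n_pos))
        i = j
    return 100.0 * float(auc), np.asarray(pts)
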