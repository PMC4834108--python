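"""Evaluation metrics: confusion statistics, McNemar's test, ROC reports,
and the cup-to-disc-ratio geometric baseline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .selection import auc as _rank_auc


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def acc_sn_sp(c: ConfusionCounts) -> tuple:
    """Accuracy, sensitivity (TP rate) and specificity (TN rate), as
    percentages.

    Acc = (TN+TP)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP).  A zero
    denominator yields ``nan`` for that metric.
    """
    total = c.total
    acc = 100.0 * (c.TN + c.TP) / total if total else float("nan")
    sn = 100.0 * c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    sp = 100.0 * c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    return acc, sn, sp


@dataclass(frozen=True)
class McNemarResult:
    c1_err: int
    c2_err: int
    chi2: float
    p_value: float
    defined: bool = True

    def significant(self, alpha: float = 0.05) -> bool:
        return self.defined and self.p_value <= alpha


#: continuity-corrected chi-squared thresholds (df=1) for p <= 0.10/0.05/0.01
CHI2_THRESHOLDS = {0.10: 2.706, 0.05: 3.841, 0.01: 6.635}


def mcnemar(c1_err: int, c2_err: int) -> McNemarResult:
    """Continuity-corrected McNemar chi-squared from the two methods'
    misclassification counts:

        chi2 = (|c1 - c2| - 1)^2 / (c1 + c2),  df = 1.

    Both counts zero is undefined and returns p = 1 with ``defined=False``.
    Symmetric in its arguments.
    """
    if c1_err < 0 or c2_err < 0:
        raise ValueError("error counts must be non-negative")
    if c1_err + c2_err == 0:
        return McNemarResult(c1_err, c2_err, 0.0, 1.0, defined=False)
    chi2 = (abs(c1_err - c2_err) - 1.0) ** 2 / (c1_err + c2_err)
    p = float(sps.chi2.sf(chi2, df=1))
    return McNemarResult(c1_err, c2_err, float(chi2), p)


def cdr_classify(vertical_cdr: float, cutoff: float = 0.55) -> str:
    """Geometric baseline: glaucoma iff CDR strictly exceeds the cutoff."""
    if not 0.0 < vertical_cdr < 1.0:
        raise ValueError(f"CDR must be in (0,1), got {vertical_cdr}")
    return "glaucoma" if vertical_cdr > cutoff else "normal"


@dataclass
class ROCReport:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_report(scores, labels) -> ROCReport:
    """ROC curve (threshold sweep over the unique scores) plus rank AUC."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("ROC needs both classes present")
    y01 = (y == classes[-1]).astype(int)
    fpr, tpr, thr = roc_curve(y01, scores)
    return ROCReport(fpr=fpr, tpr=tpr, thresholds=thr,
                     auc=_rank_auc(scores, y))
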