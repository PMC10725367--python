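"""Confusion-matrix metric suite for binary lesion classification.

All rate metrics are reported as percentages (0-100); MCC is a percentage
too for consistency with the rest of the suite.  A metric whose denominator
is zero is reported as NaN and flagged in ``undefined`` rather than being
silently set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

POSITIVE = 1  # malignant is the positive class


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    f1: float
    mcc: float
    undefined: tuple = field(default=())

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "tp", "fp", "tn", "fn", "accuracy", "sensitivity", "specificity",
            "precision", "recall", "npv", "fpr", "fdr", "fnr", "f1", "mcc")}
        d["undefined"] = list(self.undefined)
        return d


def _ratio(num, den, undefined, name):
    if den == 0:
        undefined.append(name)
        return float("nan")
    return 100.0 * num / den


def f1_score(precision_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of precision and sensitivity, all in percent."""
    if precision_pct + sensitivity_pct == 0:
        return float("nan")
    return 2.0 * precision_pct * sensitivity_pct / (precision_pct + sensitivity_pct)


def report_from_counts(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    undefined: list[str] = []
    total = tp + fp + tn + fn
    accuracy = _ratio(tp + tn, total, undefined, "accuracy")
    sensitivity = _ratio(tp, tp + fn, undefined, "sensitivity")
    specificity = _ratio(tn, tn + fp, undefined, "specificity")
    precision = _ratio(tp, tp + fp, undefined, "precision")
    npv = _ratio(tn, tn + fn, undefined, "npv")
    fpr = 100.0 - specificity if np.isfinite(specificity) else float("nan")
    fdr = 100.0 - precision if np.isfinite(precision) else float("nan")
    fnr = 100.0 - sensitivity if np.isfinite(sensitivity) else float("nan")
    if np.isfinite(precision) and np.isfinite(sensitivity):
        f1 = f1_score(precision, sensitivity)
    else:
        undefined.append("f1")
        f1 = float("nan")
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        undefined.append("mcc")
        mcc = float("nan")
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / denom
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                      sensitivity=sensitivity, specificity=specificity,
                      precision=precision, recall=sensitivity, npv=npv,
                      fpr=fpr, fdr=fdr, fnr=fnr, f1=f1, mcc=mcc,
                      undefined=tuple(undefined))


def evaluate(predictions, labels) -> EvalReport:
    """Confusion counts and all metrics for binary predictions vs labels."""
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(((p == POSITIVE) & (y == POSITIVE)).sum())
    tn = int(((p != POSITIVE) & (y != POSITIVE)).sum())
    fp = int(((p == POSITIVE) & (y != POSITIVE)).sum())
    fn = int(((p != POSITIVE) & (y == POSITIVE)).sum())
    return report_from_counts(tp, fp, tn, fn)
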