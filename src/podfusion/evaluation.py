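"""Evaluation: confusion matrices, macro metrics, Wilson intervals.

Per-class metrics come from the one-vs-rest reduction of the 4x4 confusion
matrix (rows = true class, columns = predicted class):

    accuracy  = trace / total
    recall_c    = TP_c / (TP_c + FN_c)
    precision_c = TP_c / (TP_c + FP_c)
    F1_c        = 2 * precision_c * recall_c / (precision_c + recall_c)

Macro averages are unweighted class means (classes are balanced by design).
A class never predicted gets precision 0 by convention and is flagged.

The Wilson score interval for a binomial proportion p-hat on n trials at
confidence level 1 - alpha uses the two-sided normal quantile z:

    center     = (p + z^2 / 2n) / (1 + z^2 / n)
    half-width = z * sqrt(p(1-p)/n + z^2 / 4n^2) / (1 + z^2 / n)

clamped to [0, 1].  No continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import PodfusionError, ShapeError

N_CLASSES = 4


def confusion(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int = N_CLASSES
) -> np.ndarray:
    """Counts[i, j] = number of samples with true class i predicted as j."""
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape or y.ndim != 1:
        raise ShapeError(f"label vectors differ: {y.shape} vs {p.shape}")
    for name, v in (("true", y), ("predicted", p)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise PodfusionError(f"{name} labels outside 0..{n_classes - 1}")
    return _sk_confusion(y, p, labels=np.arange(n_classes)).astype(int)


@dataclass
class EvalReport:
    """Accuracy plus per-class and macro precision/recall/F1, all fractions."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    support: np.ndarray
    never_predicted: list[int] = field(default_factory=list)
    wilson_95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "support": self.support.tolist(),
            },
            "never_predicted_classes": self.never_predicted,
        }
        if self.wilson_95 is not None:
            d["wilson_95"] = list(self.wilson_95)
        return d


def metrics(matrix: np.ndarray, with_wilson: bool = True) -> EvalReport:
    """Compute the evaluation report from a confusion matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ShapeError(f"confusion matrix must be square, got {m.shape}")
    total = m.sum()
    if total <= 0:
        raise PodfusionError("empty confusion matrix: nothing evaluated")
    tp = np.diag(m)
    pred_pos = m.sum(axis=0)
    true_pos = m.sum(axis=1)
    never = [int(c) for c in np.flatnonzero(pred_pos == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(true_pos > 0, tp / true_pos, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    accuracy = float(tp.sum() / total)
    report = EvalReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        support=true_pos.astype(int),
        never_predicted=never,
    )
    if with_wilson:
        report.wilson_95 = wilson_interval(int(total), accuracy, 0.95)
    return report


def wilson_interval(n: int, p_hat: float, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion; returns (lower, upper) fractions."""
    if not 0 < level < 1:
        raise PodfusionError(f"confidence level {level} outside (0, 1)")
    if n < 1:
        raise PodfusionError(f"need n >= 1 trials, got {n}")
    if not 0 <= p_hat <= 1:
        raise PodfusionError(f"proportion {p_hat} outside [0, 1]")
    z = norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z * z / n
    center = (p_hat + z * z / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def percent_change(v_start: float, v_end: float) -> float:
    """Signed percent change 100 * (v_end - v_start) / v_start.

    Negative values are reported in the domain as a "decrease rate" of the
    same magnitude (e.g. soluble sugar 12.64 -> 7.22 is a 42.88% decrease).
    """
    if v_start == 0:
        raise PodfusionError("percent change undefined for a zero start value")
    return 100.0 * (v_end - v_start) / v_start
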