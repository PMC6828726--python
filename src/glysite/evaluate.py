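"""Two-stage score integration and performance measures.

The protein-level voting score adjusts the sequon-level SVM scores: below
0.4 the protein looks like a non-glycoprotein and every sequon score in it is
reduced by 20% (x0.8); above 0.8 it looks like a glycoprotein and scores are
increased by 10% (x1.1, capped at 1); in between, and when the protein score
is undefined, scores pass through unchanged.  A sequon is called a glycosite
when its final score exceeds 0.6.

Metrics are the standard confusion-matrix measures (accuracy, precision,
sensitivity, specificity, MCC) plus a ROC curve traced at 1000 evenly spaced
cutoffs in [0, 1] with trapezoidal AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

STAGE1_LOW = 0.4
STAGE1_HIGH = 0.8
DOWN_FACTOR = 0.8
UP_FACTOR = 1.1
FINAL_THRESHOLD = 0.6


def adjust_scores(
    stage2_scores: Sequence[float],
    stage1_score: float | None,
    low: float = STAGE1_LOW,
    high: float = STAGE1_HIGH,
    down: float = DOWN_FACTOR,
    up: float = UP_FACTOR,
    additive: bool = False,
) -> np.ndarray:
    """Adjust a protein's sequon scores by its stage-one score.

    Strict inequalities as stated: exactly 0.4 or 0.8 falls in the unchanged
    band.  ``additive=True`` switches the -20%/+10% reading from
    multiplicative factors to absolute offsets (-0.2/+0.1); results are
    clipped to [0, 1] either way.  An undefined (None/NaN) stage-one score
    leaves the scores untouched.
    """
    s2 = np.asarray(stage2_scores, dtype=float)
    if np.any((s2 < 0) | (s2 > 1)):
        raise ValueError("stage-two scores must lie in [0, 1]")
    if stage1_score is None or (isinstance(stage1_score, float) and math.isnan(stage1_score)):
        return s2.copy()
    if stage1_score < low:
        out = s2 + (down - 1.0) if additive else s2 * down
    elif stage1_score > high:
        out = s2 + (up - 1.0) if additive else s2 * up
    else:
        out = s2.copy()
    return np.clip(out, 0.0, 1.0)


def final_calls(final_scores: Sequence[float], threshold: float = FINAL_THRESHOLD) -> np.ndarray:
    """Glycosite calls: final score strictly above the threshold."""
    return np.asarray(final_scores, dtype=float) > threshold


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PredictionRecord:
    """Per-sequon prediction: both stage scores, the adjusted final score and
    the call.  ``stage1_score`` is NaN when the protein had no templates."""

    protein_id: str
    position: int
    stage2_score: float
    stage1_score: float
    final_score: float
    call: bool


def confusion(calls: Sequence[bool], labels: Sequence[int]) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix of binary calls against binary labels."""
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {labels.shape}")
    pos = labels == 1
    return ConfusionMatrix(
        tp=int((calls & pos).sum()),
        fp=int((calls & ~pos).sum()),
        tn=int((~calls & ~pos).sum()),
        fn=int((~calls & pos).sum()),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity and MCC of a matrix.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when any
    factor of the denominator is zero the MCC is reported as 0 (convention
    for the undefined case).  Ratios with a zero denominator are NaN.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {
        "accuracy": (tp + tn) / cm.total,
        "precision": _ratio(tp, tp + fp),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "mcc": mcc,
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], n_cutoffs: int = 1000
) -> tuple[np.ndarray, float]:
    """ROC curve over evenly spaced cutoffs in [0, 1] and trapezoidal AUC.

    At each cutoff t a score >= t is called positive.  Returns an array of
    (cutoff, fpr, tpr) rows ordered by cutoff, and the AUC computed by the
    trapezoidal rule over the curve (with (0,0) and (1,1) end points).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    cutoffs = np.linspace(0.0, 1.0, n_cutoffs)
    calls = scores[None, :] >= cutoffs[:, None]
    tpr = (calls & (labels == 1)).sum(axis=1) / n_pos
    fpr = (calls & (labels == 0)).sum(axis=1) / n_neg
    curve = np.column_stack([cutoffs, fpr, tpr])
    xs = np.concatenate([[0.0], fpr[::-1], [1.0]])
    ys = np.concatenate([[0.0], tpr[::-1], [1.0]])
    order = np.argsort(xs, kind="stable")
    auc = float(np.trapezoid(ys[order], xs[order]))
    return curve, auc


def evaluate_predictions(
    records: Sequence[PredictionRecord], labels: Sequence[int]
) -> dict[str, object]:
    """Confusion matrix, the five measures, ROC points and AUC in one report."""
    calls = [r.call for r in records]
    scores = [r.final_score for r in records]
    cm = confusion(calls, labels)
    report: dict[str, object] = {"confusion": cm, **metrics(cm)}
    if len(set(np.asarray(labels).tolist())) == 2:
        curve, auc = roc_auc(scores, labels)
        report["roc_curve"] = curve
        report["auc"] = auc
    return report
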