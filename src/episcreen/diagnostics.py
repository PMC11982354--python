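"""ROC curves and AUC for scalar diagnostic markers.

AUC is computed two ways on purpose: the curve's trapezoidal integral and
the tie-corrected Mann–Whitney probability P(score_pos > score_neg) +
P(tie)/2. The two are mathematically identical, which the test suite
exploits as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = ["ROCCurve", "roc", "auc_mannwhitney"]


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    direction: str  # 'higher-in-positive' | 'lower-in-positive'


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = np.isin(y, ("positive", "pos", "tumor", "1", "True", "true"))
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def roc(scores, labels, direction: str = "higher-in-positive") -> ROCCurve:
    """ROC curve over the unique score thresholds, with trapezoidal AUC.

    ``direction`` states which orientation marks the positive class;
    ``'auto'`` picks the orientation with AUC >= 0.5 and records the choice
    in the returned curve.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if direction == "auto":
        direction = (
            "higher-in-positive"
            if auc_mannwhitney(s, y) >= 0.5
            else "lower-in-positive"
        )
    if direction == "lower-in-positive":
        oriented = -s
    elif direction == "higher-in-positive":
        oriented = s
    else:
        raise ValueError(f"unknown direction {direction!r}")
    fpr, tpr, thr = roc_curve(y, oriented, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thr, fpr, tpr, auc, direction)


def auc_mannwhitney(scores, labels) -> float:
    """Tie-corrected AUC = (U + ties/2) / (n_pos * n_neg) via average ranks."""
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
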