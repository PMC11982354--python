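"""Closed-form bench-assay computations.

Relative qPCR expression by the 2^-ddCt method, knockdown percentage,
ellipsoid tumor volume from caliper measurements, and the three-level
immunohistochemistry positivity score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "knockdown_percent", "tumor_volume", "ihc_score"]


def ddct_fold_change(records: pd.DataFrame, condition: str, calibrator: str) -> float:
    """Relative expression 2^-ddCt of ``condition`` vs ``calibrator``.

    ``records`` needs columns ``condition``, ``ct_target``, ``ct_control``
    (endogenous-control Ct, e.g. GAPDH). Per condition,
    dCt = mean(Ct_target) - mean(Ct_control); ddCt = dCt_cond - dCt_cal.
    """
    for col in ("condition", "ct_target", "ct_control"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    cts = records[["ct_target", "ct_control"]].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise ValueError("Ct values must be finite and positive")

    def dct(name: str) -> float:
        sub = records[records["condition"] == name]
        if sub.empty:
            raise ValueError(f"condition {name!r} absent from records")
        return float(sub["ct_target"].mean() - sub["ct_control"].mean())

    ddct = dct(condition) - dct(calibrator)
    return float(2.0 ** (-ddct))


def knockdown_percent(fold_change: float) -> float:
    """Knockdown as (1 - fold_change) * 100, floored at 0."""
    if fold_change < 0:
        raise ValueError("fold change must be non-negative")
    return max(0.0, (1.0 - fold_change) * 100.0)


def tumor_volume(length: float, width: float, height: float) -> float:
    """Ellipsoid caliper volume pi/6 * length * width * height (mm^3)."""
    if min(length, width, height) <= 0:
        raise ValueError("all dimensions must be positive")
    return float(np.pi / 6.0 * length * width * height)


def ihc_score(percent_positive: float) -> int:
    """Three-level IHC positivity score.

    <1% positive cells -> 1 (absent/low); 1-20% inclusive -> 2 (medium);
    >20% -> 3 (high).
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError("percentage must lie in [0, 100]")
    if percent_positive < 1:
        return 1
    if percent_positive <= 20:
        return 2
    return 3
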