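"""Shared rank-test and multiple-testing machinery.

Both the methylation and the expression callers use the same two-group
Wilcoxon–Mann–Whitney test: exact two-sided p-values for small tie-free
groups, otherwise the normal approximation with tie and continuity
correction. Benjamini–Hochberg adjustment is delegated to statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["mannwhitney_rows", "bh_adjust"]

# Largest min-group size for which the exact null distribution is used.
_EXACT_MAX_N = 8


def _row_has_ties(row: np.ndarray) -> bool:
    s = np.sort(row)
    return bool(np.any(s[1:] == s[:-1]))


def mannwhitney_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon–Mann–Whitney p-value for each row of ``a`` vs ``b``.

    Parameters
    ----------
    a, b
        Arrays of shape (n_units, n1) and (n_units, n2); each row is one
        feature measured in the two groups.

    Returns
    -------
    ndarray of p-values, one per row. Rows whose pooled values are all
    identical carry no ordering information and get p = 1.

    Exact enumeration is used when ``min(n1, n2) <= 8`` and the pooled row
    is tie-free; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("group arrays must have the same number of rows")
    n1, n2 = a.shape[1], b.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")

    pooled = np.concatenate([a, b], axis=1)
    degenerate = np.ptp(pooled, axis=1) == 0

    p = np.ones(a.shape[0])
    ok = ~degenerate
    if np.any(ok):
        res = stats.mannwhitneyu(
            a[ok], b[ok], axis=1, alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        p[ok] = res.pvalue

    if min(n1, n2) <= _EXACT_MAX_N:
        for i in np.flatnonzero(ok):
            if not _row_has_ties(pooled[i]):
                p[i] = stats.mannwhitneyu(
                    a[i], b[i], alternative="two-sided", method="exact"
                ).pvalue
    return np.clip(p, 0.0, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Order-preserving, capped at 1; NaN inputs are rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not adjustable")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    q = multipletests(flat, method="fdr_bh")[1]
    return q.reshape(p.shape)
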