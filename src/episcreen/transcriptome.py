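"""Count normalization (TPM/FPKM) and differential expression calling.

Expression testing runs on TPM rather than raw counts: the rank test used
here is invariant to monotone per-sample scalings, so either works, but TPM
is the unit reported downstream. The log2 fold change between group means
uses the small pseudocount 1e-4, the same constant used for the
log2(FPKM + 1e-4) display transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, mannwhitney_rows

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "normalize",
    "de_test",
    "call_de",
    "bh_adjust",
    "PSEUDOCOUNT",
    "DE_LFC",
]

#: pseudocount shared by the log transform and the fold-change ratio
PSEUDOCOUNT = 1e-4

#: |log2FC| threshold for a significant expression call
DE_LFC = 1.0


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with gene lengths (bp)."""

    counts: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series
    patients: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        lens = self.lengths.reindex(self.counts.index)
        if lens.isna().any() or (lens <= 0).any():
            raise ValueError("every gene needs a positive length")
        missing = self.counts.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {list(missing)[:5]}")

    def group_columns(self, group: str) -> pd.Index:
        g = self.groups.loc[self.counts.columns]
        return self.counts.columns[g == group]


@dataclass
class NormalizedMatrix:
    """Gene x sample normalized expression with a unit tag."""

    values: pd.DataFrame
    unit: str  # 'TPM' | 'FPKM' | 'logFPKM'
    groups: pd.Series
    patients: pd.Series | None = None

    def group_columns(self, group: str) -> pd.Index:
        g = self.groups.loc[self.values.columns]
        return self.values.columns[g == group]


def normalize(counts: CountMatrix, method: str = "TPM") -> NormalizedMatrix:
    """Normalize counts to TPM, FPKM or log2(FPKM + 1e-4).

    FPKM = count * 1e9 / (length * column_total); TPM rescales the
    length-normalized rates so each column sums to one million.
    """
    if method not in {"TPM", "FPKM", "logFPKM"}:
        raise ValueError(f"unknown method {method!r}")
    c = counts.counts.to_numpy(dtype=float)
    lens = counts.lengths.reindex(counts.counts.index).to_numpy(dtype=float)
    totals = c.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = counts.counts.columns[zero][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    if method == "TPM":
        rate = c / lens[:, None]
        vals = rate / rate.sum(axis=0, keepdims=True) * 1e6
    else:
        vals = c * 1e9 / (lens[:, None] * totals[None, :])
        if method == "logFPKM":
            vals = np.log2(vals + PSEUDOCOUNT)
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return NormalizedMatrix(df, method, counts.groups, counts.patients)


def de_test(norm: NormalizedMatrix) -> pd.DataFrame:
    """Differential expression tumor vs normal by Wilcoxon–Mann–Whitney.

    Effect = log2((mean_tumor + c) / (mean_normal + c)) with c = 1e-4;
    q-values by Benjamini–Hochberg.
    """
    t_cols = norm.group_columns("tumor")
    n_cols = norm.group_columns("normal")
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    vt = norm.values[t_cols].to_numpy()
    vn = norm.values[n_cols].to_numpy()
    mt, mn = vt.mean(axis=1), vn.mean(axis=1)
    effect = np.log2((mt + PSEUDOCOUNT) / (mn + PSEUDOCOUNT))
    p = mannwhitney_rows(vt, vn)
    return pd.DataFrame(
        {
            "gene": norm.values.index,
            "mean_tumor": mt,
            "mean_normal": mn,
            "lfc": effect,
            "p": p,
            "q": bh_adjust(p),
        }
    ).reset_index(drop=True)


def call_de(records: pd.DataFrame) -> pd.DataFrame:
    """Significant expression calls: p <= 0.05 and |log2FC| >= 1 (inclusive).

    Returns the significant subset with a ``direction`` column
    ('up'/'down') partitioning it.
    """
    rec = records.copy()
    rec["significant"] = (rec["p"] <= 0.05) & (rec["lfc"].abs() >= DE_LFC)
    rec["direction"] = np.where(
        ~rec["significant"], "", np.where(rec["lfc"] > 0, "up", "down")
    )
    return rec[rec["significant"]].reset_index(drop=True)
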