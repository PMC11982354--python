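"""Beta/M-value handling and differential methylation calling.

Methylation at a CpG probe is summarized by the beta value, the fraction of
methylated signal in [0, 1]. Statistical testing is done on the M-value
scale, M = logit2(beta) = log2(methylated/unmethylated), which stabilizes
variance near the boundaries. Probes are aggregated to genes by the
arithmetic mean of their beta values, and tumor-vs-normal differences are
assessed with the Wilcoxon–Mann–Whitney test on M-values, with
Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, mannwhitney_rows

__all__ = [
    "BetaMatrix",
    "GeneMethylation",
    "REGION_CLASSES",
    "beta_to_m",
    "m_to_beta",
    "aggregate_gene",
    "region_methylation",
    "dm_test",
    "call_dm",
    "LOGIT_EPS",
    "GENE_DM_LFC",
    "ISLAND_DM_FC",
]

#: epsilon used to clip beta before the logit so boundary betas stay finite
LOGIT_EPS = 1e-6

#: |delta-M| threshold for a significant gene-level call
GENE_DM_LFC = 0.5

#: linear fold-change threshold at probe/island level; applied as
#: |delta-M| >= log2(ISLAND_DM_FC), reading the fold change as a ratio of
#: methylated/unmethylated odds (see docs/methods.md)
ISLAND_DM_FC = 1.45

#: Infinium-450k-style CpG region classes relative to the nearest island
REGION_CLASSES = ("island", "shore_N", "shore_S", "shelf_N", "shelf_S", "open_sea")


@dataclass
class BetaMatrix:
    """Probe x sample beta values plus probe annotation and sample groups.

    ``values``: DataFrame indexed by probe id, columns = sample ids.
    ``annotation``: DataFrame indexed by probe id with columns
    ``gene`` (symbol, may be NA), ``chrom``, ``pos``, ``region``
    (one of :data:`REGION_CLASSES`).
    ``groups``: Series over sample ids with values 'tumor'/'normal'.
    ``patients``: optional Series mapping sample id -> patient id for
    paired designs.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    groups: pd.Series
    patients: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {list(missing)[:5]}")
        bad = set(self.groups.loc[self.values.columns]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def group_columns(self, group: str) -> pd.Index:
        g = self.groups.loc[self.values.columns]
        return self.values.columns[g == group]


@dataclass
class GeneMethylation:
    """Gene x sample mean beta over each gene's probes."""

    values: pd.DataFrame
    probe_counts: pd.Series
    groups: pd.Series
    patients: pd.Series | None = None

    def group_columns(self, group: str) -> pd.Index:
        g = self.groups.loc[self.values.columns]
        return self.values.columns[g == group]


def beta_to_m(beta, eps: float = LOGIT_EPS):
    """M-value logit2 transform: log2(b / (1 - b)) with b clipped to [eps, 1-eps].

    Strictly increasing on [0, 1]; inputs outside [0, 1] are an error.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1 - eps)
    out = np.log2(b / (1 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


def aggregate_gene(matrix: BetaMatrix) -> GeneMethylation:
    """Mean beta per gene per sample over the gene's probes.

    Probes without a gene symbol are excluded; genes that end up with zero
    probes are absent from the output.
    """
    ann = matrix.annotation
    if ann.empty:
        raise ValueError("probe annotation is empty")
    gene = ann["gene"].reindex(matrix.values.index)
    keep = gene.notna() & (gene.astype(str).str.len() > 0)
    if not keep.any():
        raise ValueError("no probe maps to a gene symbol")
    vals = matrix.values.loc[keep]
    by = gene[keep]
    agg = vals.groupby(by, sort=True).mean()
    counts = vals.groupby(by, sort=True).size()
    agg.index.name = "gene"
    return GeneMethylation(agg, counts, matrix.groups, matrix.patients)


def region_methylation(matrix: BetaMatrix, gene: str):
    """Group-wise mean beta per CpG region class for one gene.

    Returns ``(table, absent)`` where ``table`` is a DataFrame indexed by the
    region classes that have at least one probe (columns 'tumor'/'normal')
    and ``absent`` lists the classes with no probe for this gene.
    """
    ann = matrix.annotation
    sel = ann.index[(ann["gene"] == gene)]
    sel = sel.intersection(matrix.values.index)
    if len(sel) == 0:
        raise KeyError(f"gene {gene!r} has no annotated probes")
    rows = {}
    for group in ("tumor", "normal"):
        cols = matrix.group_columns(group)
        sub = matrix.values.loc[sel, cols]
        rows[group] = sub.groupby(ann.loc[sel, "region"]).mean().mean(axis=1)
    table = pd.DataFrame(rows)
    present = [c for c in REGION_CLASSES if c in table.index]
    table = table.loc[present]
    absent = [c for c in REGION_CLASSES if c not in table.index]
    return table, absent


def _dm_frame(values: pd.DataFrame, groups: pd.Series, level: str) -> pd.DataFrame:
    cols = values.columns
    g = groups.loc[cols]
    t_cols = cols[g == "tumor"]
    n_cols = cols[g == "normal"]
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    # toy-scale missing-value policy: drop units with any missing beta
    complete = values.notna().all(axis=1)
    vals = values.loc[complete]
    m = beta_to_m(vals.to_numpy())
    m = pd.DataFrame(m, index=vals.index, columns=vals.columns)
    mt = m[t_cols].to_numpy()
    mn = m[n_cols].to_numpy()
    effect = mt.mean(axis=1) - mn.mean(axis=1)
    p = mannwhitney_rows(mt, mn)
    out = pd.DataFrame(
        {
            "unit": vals.index,
            "level": level,
            "m_mean_tumor": mt.mean(axis=1),
            "m_mean_normal": mn.mean(axis=1),
            "lfc": effect,
            "p": p,
            "q": bh_adjust(p),
        }
    ).reset_index(drop=True)
    return out


def dm_test(matrix, level: str = "gene") -> pd.DataFrame:
    """Differential methylation on M-values, tumor vs normal.

    ``matrix`` is a :class:`BetaMatrix` (``level='probe'``) or a
    :class:`GeneMethylation` (``level='gene'``). The effect ``lfc`` is the
    difference of group-mean M-values (itself a log2 fold change of the
    methylated/unmethylated ratio); ``p`` from the Wilcoxon–Mann–Whitney
    test, ``q`` by Benjamini–Hochberg.
    """
    if level not in {"probe", "gene"}:
        raise ValueError("level must be 'probe' or 'gene'")
    if isinstance(matrix, BetaMatrix) and level == "gene":
        matrix = aggregate_gene(matrix)
    return _dm_frame(matrix.values, matrix.groups, level)


def call_dm(records: pd.DataFrame, level: str = "gene") -> pd.DataFrame:
    """Flag significant differentially methylated units.

    Gene level: p <= 0.05 and |lfc| >= 0.5. Probe/island level: p <= 0.05
    and |lfc| >= log2(1.45). Comparisons are inclusive. Adds boolean
    ``significant`` and ``direction`` ('hyper'/'hypo'/'') columns and
    returns the significant subset.
    """
    thr = GENE_DM_LFC if level == "gene" else float(np.log2(ISLAND_DM_FC))
    rec = records.copy()
    rec["significant"] = (rec["p"] <= 0.05) & (rec["lfc"].abs() >= thr)
    rec["direction"] = np.where(
        ~rec["significant"], "", np.where(rec["lfc"] > 0, "hyper", "hypo")
    )
    return rec[rec["significant"]].reset_index(drop=True)
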