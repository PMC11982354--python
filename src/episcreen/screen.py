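"""Integrative methylation–expression screen and enrichment analysis.

The screen looks for candidate tumor suppressors: genes simultaneously
hypermethylated (delta-M >= 0.5, p <= 0.05) and down-expressed
(log2FC <= -1, p <= 0.05) in tumor vs normal. Hits from two cohorts are
intersected, methylation–expression correlations are computed, and
over-representation against user-supplied gene sets (GMT) is assessed with
the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "ScreenThresholds",
    "OverlapResult",
    "CorrelationResult",
    "screen_cohort",
    "intersect_cohorts",
    "correlate",
    "ora",
    "read_gmt",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """Dual significance cut-offs defining a screen hit (all inclusive)."""

    de_p: float = 0.05
    de_lfc: float = -1.0  # expression log2FC at or below this (down)
    dm_p: float = 0.05
    dm_lfc: float = 0.5  # methylation delta-M at or above this (hyper)


@dataclass
class OverlapResult:
    """Hit sets of two cohorts and their intersection (Venn counts)."""

    hits_a: set
    hits_b: set
    intersection: list
    counts: dict = field(init=False)

    def __post_init__(self) -> None:
        both = len(self.intersection)
        self.counts = {
            "a": len(self.hits_a),
            "b": len(self.hits_b),
            "both": both,
            "only_a": len(self.hits_a) - both,
            "only_b": len(self.hits_b) - both,
        }


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int


def screen_cohort(
    de_records: pd.DataFrame,
    dm_records: pd.DataFrame,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> pd.DataFrame:
    """Join expression and methylation records per gene and flag hits.

    Genes present on only one side are excluded (count logged). Each gene
    gets a ``quadrant`` from the effect signs at joint significance and an
    ``is_hit`` flag for the hyper-down quadrant at the stated thresholds.
    """
    de = de_records.set_index("gene")[["lfc", "p"]].rename(
        columns={"lfc": "de_lfc", "p": "de_p"}
    )
    dm_key = "unit" if "unit" in dm_records.columns else "gene"
    dm = dm_records.set_index(dm_key)[["lfc", "p"]].rename(
        columns={"lfc": "dm_lfc", "p": "dm_p"}
    )
    common = de.index.intersection(dm.index)
    dropped = (len(de) - len(common)) + (len(dm) - len(common))
    if len(common) == 0:
        raise ValueError("expression and methylation records share no gene")
    if dropped:
        log.info("screen_cohort: %d one-sided gene records excluded", dropped)
    tab = de.loc[common].join(dm.loc[common])
    sig = (tab["de_p"] <= thresholds.de_p) & (tab["dm_p"] <= thresholds.dm_p)
    meth = np.where(tab["dm_lfc"] >= 0, "hyper", "hypo")
    expr = np.where(tab["de_lfc"] <= 0, "down", "up")
    quad = np.where(sig, np.char.add(np.char.add(meth, "-"), expr), "non-significant")
    hit = (
        (tab["de_p"] <= thresholds.de_p)
        & (tab["de_lfc"] <= thresholds.de_lfc)
        & (tab["dm_p"] <= thresholds.dm_p)
        & (tab["dm_lfc"] >= thresholds.dm_lfc)
    )
    out = tab.reset_index().rename(columns={"index": "gene", dm_key: "gene"})
    out["quadrant"] = quad
    out["is_hit"] = hit.to_numpy()
    return out


def intersect_cohorts(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> OverlapResult:
    """Intersect the hit gene sets of two cohort screens."""
    ha = set(calls_a.loc[calls_a["is_hit"], "gene"])
    hb = set(calls_b.loc[calls_b["is_hit"], "gene"])
    return OverlapResult(ha, hb, sorted(ha & hb))


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson R or Spearman rho with its p-value.

    Spearman is Pearson on average ranks; p-values come from the
    t-distribution machinery of scipy's correlation tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r), float(p), len(x))


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from a GMT file: name, description, members per line."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora(hits, gene_sets: dict[str, set], universe) -> pd.DataFrame:
    """Over-representation analysis by the hypergeometric upper tail.

    For each named set, p = P(overlap >= k) drawing |hits| genes from a
    universe of size N containing K set members; BH across sets;
    ``significant`` at p < 0.05.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    n = len(hits)
    N = len(universe)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & universe)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p"] < 0.05
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
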