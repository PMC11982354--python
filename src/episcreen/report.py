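"""End-to-end pipeline orchestration and summary reporting.

Stage results are tallied the way the screen's summary tables print them:
counts with percentages rounded half-away-from-zero to one decimal
(62.2% / 37.8% style). ``run_pipeline`` wires the stages together from a
config, writes every intermediate table, and emits a deterministic
machine-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, methylome, screen, survival, transcriptome

__all__ = ["RunConfig", "round_percent", "summarize_de", "summarize_dm", "run_pipeline"]

log = logging.getLogger(__name__)


def round_percent(part: float, total: float):
    """100*part/total rounded half-away-from-zero to one decimal.

    Returns None (reported as undefined) for a zero total, never 0.0.
    """
    if total == 0:
        return None
    pct = Decimal(100 * part) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_de(records: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Tally of an expression run: tested/significant counts, up/down split."""
    n_up = int((calls["direction"] == "up").sum())
    n_down = int((calls["direction"] == "down").sum())
    n_sig = len(calls)
    return {
        "n_tested": len(records),
        "n_significant": n_sig,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": round_percent(n_up, n_sig),
        "pct_down": round_percent(n_down, n_sig),
    }


def summarize_dm(records: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Tally of a methylation run: hyper/hypo split of the significant calls."""
    n_hyper = int((calls["direction"] == "hyper").sum())
    n_hypo = int((calls["direction"] == "hypo").sum())
    n_sig = len(calls)
    return {
        "n_tested": len(records),
        "n_significant": n_sig,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": round_percent(n_hyper, n_sig),
        "pct_hypo": round_percent(n_hypo, n_sig),
    }


@dataclass
class RunConfig:
    """Inputs, thresholds and options of an end-to-end run."""

    counts_path: str
    beta_path: str
    annotation_path: str
    samples_path: str
    out_dir: str
    survival_path: str | None = None
    roc_gene: str | None = None  # marker gene for the diagnostic stage
    roc_direction: str = "lower-in-positive"
    de_p: float = 0.05
    de_lfc: float = 1.0
    dm_p: float = 0.05
    dm_lfc: float = 0.5
    island_fc: float = 1.45
    survival_quantiles: tuple[float, float, float] = (0.10, 0.90, 0.05)
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_p", "de_lfc", "dm_p", "dm_lfc", "island_fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        lo, hi, step = self.survival_quantiles
        if not (0 < lo < hi < 1 and step > 0):
            raise ValueError("survival quantile grid must satisfy 0 < lo < hi < 1, step > 0")


def _read_inputs(cfg: RunConfig):
    counts_tab = pd.read_csv(cfg.counts_path, sep="\t", index_col=0)
    if "length" not in counts_tab.columns:
        raise ValueError("counts TSV needs a 'length' column")
    lengths = counts_tab.pop("length")
    sheet = pd.read_csv(cfg.samples_path)
    groups = pd.Series(sheet["group"].values, index=sheet["sample"])
    beta_tab = pd.read_csv(cfg.beta_path, sep="\t", index_col=0)
    ann = pd.read_csv(cfg.annotation_path, sep="\t", index_col=0)
    cm = transcriptome.CountMatrix(counts_tab, lengths, groups)
    bm = methylome.BetaMatrix(beta_tab, ann, groups)
    return cm, bm


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute normalize -> DE/DM -> screen -> correlate -> ROC -> survival.

    Writes every stage table under ``cfg.out_dir`` plus ``report.json``;
    returns the report dict. Reruns with the same config and inputs are
    byte-identical. Any stage failure raises with the stage name; tables
    written before the failure are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()}}

    stage = "inputs"
    try:
        cm, bm = _read_inputs(cfg)

        stage = "normalize"
        norm = transcriptome.normalize(cm, "TPM")
        norm.values.to_csv(out / "tpm.tsv", sep="\t", index_label="gene")

        stage = "de"
        de = transcriptome.de_test(norm)
        de_calls = transcriptome.call_de(de)
        de.to_csv(out / "de.tsv", sep="\t", index=False)
        de_calls.to_csv(out / "de_calls.tsv", sep="\t", index=False)
        report["de"] = summarize_de(de, de_calls)

        stage = "dm"
        gm = methylome.aggregate_gene(bm)
        dm = methylome.dm_test(gm, level="gene")
        dm_calls = methylome.call_dm(dm, level="gene")
        dm.to_csv(out / "dm.tsv", sep="\t", index=False)
        dm_calls.to_csv(out / "dm_calls.tsv", sep="\t", index=False)
        report["dm"] = summarize_dm(dm, dm_calls)

        stage = "screen"
        thr = screen.ScreenThresholds(cfg.de_p, -cfg.de_lfc, cfg.dm_p, cfg.dm_lfc)
        calls = screen.screen_cohort(de, dm, thr)
        calls.to_csv(out / "screen.tsv", sep="\t", index=False)
        hits = sorted(calls.loc[calls["is_hit"], "gene"])
        report["screen"] = {"n_hits": len(hits), "hits": hits}

        stage = "correlate"
        corr = {}
        for g in hits[:20]:
            x = gm.values.loc[g].to_numpy()
            y = norm.values.loc[g].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = screen.correlate(x, y, "spearman")
            corr[g] = {"rho": res.coefficient, "p": res.p, "n": res.n}
        report["correlation"] = corr

        stage = "roc"
        if cfg.roc_gene is not None:
            scores = norm.values.loc[cfg.roc_gene].to_numpy()
            labels = (bm.groups.loc[norm.values.columns] == "tumor").to_numpy()
            curve = diagnostics.roc(scores, labels.astype(int), cfg.roc_direction)
            pd.DataFrame(
                {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
            ).to_csv(out / "roc.tsv", sep="\t", index=False)
            report["roc"] = {
                "gene": cfg.roc_gene,
                "auc": curve.auc,
                "direction": curve.direction,
            }

        stage = "survival"
        if cfg.survival_path is not None:
            surv = pd.read_csv(cfg.survival_path)
            lo, hi, step = cfg.survival_quantiles
            grid = np.arange(lo, hi + step / 2, step)
            scan = survival.best_cutoff_scan(
                surv["time"], surv["event"], surv["marker"], quantiles=grid
            )
            pd.DataFrame({"cutoff": scan.cutoffs, "p": scan.pvalues}).to_csv(
                out / "cutoff_scan.tsv", sep="\t", index=False
            )
            lo_arm = surv["marker"] <= scan.selected_cutoff
            lr = survival.logrank(
                surv.loc[lo_arm, "time"], surv.loc[lo_arm, "event"],
                surv.loc[~lo_arm, "time"], surv.loc[~lo_arm, "event"],
            )
            report["survival"] = {
                "selected_cutoff": scan.selected_cutoff,
                "selected_p": scan.selected_p,
                "hr_low_vs_high": lr.hr,
                "note": scan.note,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    text = json.dumps(report, indent=1, sort_keys=True, default=str)
    (out / "report.json").write_text(text)
    return report
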