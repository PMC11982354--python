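"""Kaplan–Meier estimation, log-rank testing, and best-cutoff dichotomization.

The marker-dichotomization scan emulates the "best cutoff" convention of
online survival tools: candidate cutoffs are marker quantiles (10%–90% in
5% steps by default), each splits the cohort in two arms, and the cutoff
with the smallest log-rank p-value is selected. That minimum p is
multiplicity-biased by construction and is flagged as such in the result.

The hazard ratio is summarized from the log-rank observed/expected counts,
HR = (O1/E1)/(O2/E2), rather than from a Cox fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutoffScan",
    "km_estimate",
    "logrank",
    "best_cutoff_scan",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class LogRankResult:
    chi2: float
    p: float
    observed: np.ndarray  # O per group
    expected: np.ndarray  # E per group
    hr: float  # (O1/E1) / (O2/E2)


@dataclass
class CutoffScan:
    cutoffs: np.ndarray
    pvalues: np.ndarray
    selected_cutoff: float
    selected_p: float
    note: str = field(
        default="minimal p over a cutoff grid; multiplicity-biased, "
        "not corrected for cutoff optimization"
    )


def _as_arrays(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return t, e


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Returns S(t) and at-risk counts at the distinct event times; records
    censored exactly at an event time count as at risk for that time.
    """
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    return KMCurve(times, surv, at_risk)


def _observed_expected(t1, e1, t2, e2):
    """O and E per group from the pooled risk-set tally at each event time."""
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = np.zeros(2)
    E = np.zeros(2)
    for tt in times:
        n1 = np.sum(t1 >= tt)
        n2 = np.sum(t2 >= tt)
        d1 = np.sum((t1 == tt) & (e1 == 1))
        d2 = np.sum((t2 == tt) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        if n == 0:
            continue
        O += (d1, d2)
        E += (d * n1 / n, d * n2 / n)
    return O, E


def logrank(time1, event1, time2, event2) -> LogRankResult:
    """Two-group log-rank chi-square (1 df) with O/E hazard-ratio summary."""
    t1, e1 = _as_arrays(time1, event1)
    t2, e2 = _as_arrays(time2, event2)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group")
    O, E = _observed_expected(t1, e1, t2, e2)
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(E > 0, O / E, np.nan)
        hr = float(rates[0] / rates[1]) if rates[1] and np.isfinite(rates).all() else np.nan
    return LogRankResult(chi2, p, O, E, hr)


def best_cutoff_scan(
    time, event, marker, quantiles=None
) -> CutoffScan:
    """Scan marker quantiles for the dichotomization minimizing log-rank p.

    Candidates default to the 10%..90% quantiles in 5% steps; candidates
    leaving an empty arm are dropped. Requires >= 20 patients and a
    non-constant marker. Ties in the minimal p resolve to the smallest
    cutoff.
    """
    t, e = _as_arrays(time, event)
    m = np.asarray(marker, dtype=float)
    if len(m) != len(t):
        raise ValueError("marker length mismatch")
    if len(t) < 20:
        raise ValueError("need at least 20 patients for a cutoff scan")
    if np.ptp(m) == 0:
        raise ValueError("constant marker cannot be dichotomized")
    if quantiles is None:
        quantiles = np.arange(0.10, 0.9001, 0.05)
    cand = np.unique(np.quantile(m, quantiles))
    cutoffs, pvals = [], []
    for c in cand:
        lo = m <= c
        hi = ~lo
        if not lo.any() or not hi.any():
            continue
        if e[lo].sum() + e[hi].sum() == 0:
            continue
        res = logrank(t[lo], e[lo], t[hi], e[hi])
        cutoffs.append(c)
        pvals.append(res.p)
    if not cutoffs:
        raise ValueError("no valid cutoff candidate")
    cutoffs = np.asarray(cutoffs)
    pvals = np.asarray(pvals)
    i = int(np.argmin(pvals))
    return CutoffScan(cutoffs, pvals, float(cutoffs[i]), float(pvals[i]))
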