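"""Multi-run statistical validation of stochastic optimizers.

Tuning runs are repeated (30 by default) with distinct seeds per optimizer;
each algorithm's per-run best objective values form a sample.  Samples are
summarized (best/worst/mean/median/std/var), screened for normality with
Shapiro-Wilk at alpha = 0.05, and — since the normality null is typically
rejected for such samples — compared pairwise against the control algorithm
with the two-sided Wilcoxon signed-rank test, pairing run i with run i
(runs share data seeds across algorithms).

The exact Wilcoxon tail for n <= 25 is computed by enumeration of the 2^n
sign assignments via a rank-sum convolution that handles midranks from ties;
larger samples use the normal approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .search_space import HyperparameterSet

__all__ = [
    "RunCollection",
    "SummaryRow",
    "summarize_runs",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "summary_frame",
]

ALPHA = 0.05


@dataclass
class RunCollection:
    """Per-run outcomes of one optimizer across repeated tuning runs."""

    algorithm: str
    objectives: list[float] = field(default_factory=list)
    indicators: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    best_hyperparameters: list[HyperparameterSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("run seeds must be distinct")


@dataclass(frozen=True)
class SummaryRow:
    best: float
    worst: float
    mean: float
    median: float
    std: float
    var: float


def summarize_runs(sample: Sequence[float], minimize: bool = True) -> SummaryRow:
    """Six-number summary of a run sample.  ``minimize`` selects whether
    'best' is the smallest (objective) or largest (indicator) value.
    Std is the sample standard deviation (denominator n - 1; 0 for n = 1)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    std = float(x.std(ddof=1)) if x.size > 1 else 0.0
    lo, hi = float(x.min()), float(x.max())
    return SummaryRow(
        best=lo if minimize else hi,
        worst=hi if minimize else lo,
        mean=float(x.mean()),
        median=float(np.median(x)),
        std=std,
        var=std**2,
    )


def shapiro_wilk(sample: Sequence[float]) -> float:
    """p-value of the Shapiro-Wilk normality test; p < 0.05 flags the sample
    as non-normal, gating the switch to nonparametric comparisons."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable beyond 5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def _exact_wilcoxon_p(double_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Two-sided exact p by counting sign assignments.

    ``double_ranks`` are 2x the midranks (integers even under ties).  The
    null distribution of the doubled positive-rank sum is built by
    convolution over all 2^n equally likely sign assignments; the two-sided
    p doubles the smaller tail (the distribution is symmetric about half the
    total)."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    w = min(w_plus_doubled, total - w_plus_doubled)
    p = 2.0 * counts[: w + 1].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    control: Sequence[float], other: Sequence[float]
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded; midranks are used for ties.  Exact
    enumeration for n <= 25 effective pairs, normal approximation with tie
    correction beyond that.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        double_ranks = np.rint(2 * ranks).astype(int)
        w_plus_doubled = int(round(2 * w_plus))
        return _exact_wilcoxon_p(double_ranks, w_plus_doubled)

    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48
    z = (w_plus - mean) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def summary_frame(
    collections: list[RunCollection], which: str = "objectives"
) -> pd.DataFrame:
    """Summary table (one row per algorithm) over objective or indicator
    samples, matching the multi-run reporting layout."""
    minimize = which == "objectives"
    rows = []
    for rc in collections:
        row = summarize_runs(getattr(rc, which), minimize=minimize)
        rows.append(
            {
                "method": rc.algorithm,
                "best": row.best,
                "worst": row.worst,
                "mean": row.mean,
                "median": row.median,
                "std": row.std,
                "var": row.var,
            }
        )
    return pd.DataFrame(rows)
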