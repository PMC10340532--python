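"""Statistics for cell-based readouts.

Micronucleus and lagging-chromosome assays score a fixed number of
cells per biological repeat (100 by convention) and report the percent
positive per repeat; comparisons between conditions use the
equal-variance Student's t-test on the replicate-level percentages (the
experimental n is the number of repeats, not the number of cells).
Colony-formation assays count colonies above a strict size cutoff,
normalize each experiment to its DMSO control, and compare the
normalized fractions to the theoretical value 1.0 with a one-sample
t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CountAssayResult",
    "proportion_summary",
    "two_sample_t",
    "count_colonies",
    "clonogenic_one_sample_t",
]


@dataclass(frozen=True)
class CountAssayResult:
    """Per-replicate positives out of n scored cells, with summary."""

    counts: tuple[int, ...]
    n_scored: int
    percents: tuple[float, ...]
    mean_percent: float
    sd_percent: float


def proportion_summary(counts, n_scored: int = 100) -> CountAssayResult:
    """Summarize per-replicate positive counts as percentages.

    Each replicate scored ``n_scored`` cells; the SD is the sample SD
    over replicates (NaN for a single replicate).
    """
    counts = tuple(int(k) for k in counts)
    if n_scored <= 0:
        raise ValueError("n_scored must be > 0")
    for k in counts:
        if not 0 <= k <= n_scored:
            raise ValueError(f"count {k} outside [0, {n_scored}]")
    pct = tuple(100.0 * k / n_scored for k in counts)
    arr = np.asarray(pct)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else math.nan
    return CountAssayResult(counts, n_scored, pct, float(arr.mean()), sd)


def two_sample_t(cond_a_percents, cond_b_percents) -> tuple[float, float]:
    """Two-sided, equal-variance Student's t-test on replicate
    percentages.  Returns (t, p).

    Degenerate zero-variance groups are handled explicitly: equal means
    give (0, 1), different means give (+/-inf, 0).
    """
    a = np.asarray(cond_a_percents, dtype=float)
    b = np.asarray(cond_b_percents, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per condition")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def count_colonies(colony_sizes, min_cells: int = 50) -> int:
    """Number of colonies with strictly more than ``min_cells`` cells."""
    return int(sum(1 for s in colony_sizes if s > min_cells))


def clonogenic_one_sample_t(normalized_fractions) -> tuple[float, float]:
    """One-sample two-sided t-test of normalized colony fractions against
    the theoretical control value 1.0.  Returns (t, p); a zero-variance
    sample at exactly 1.0 returns (0, 1)."""
    x = np.asarray(normalized_fractions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two experiments for a one-sample t-test")
    if x.std(ddof=1) == 0:
        if x.mean() == 1.0:
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - 1.0), 0.0
    t, p = stats.ttest_1samp(x, 1.0)
    return float(t), float(p)
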