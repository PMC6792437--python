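"""Regional enrichment statistics on the abundance matrix.

Each population's relative abundances in one sample group (e.g. the
Pacific Ocean metagenomes) are compared against all remaining samples
with Welch's unequal-variance t-test (degrees of freedom by
Welch-Satterthwaite). P-values are reported raw by default, with
optional Benjamini-Hochberg adjustment across populations. The test is
applied to raw relative abundances; the square-root transform is a
display convention only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


class UndefinedTestError(ValueError):
    """Both groups have zero variance — the statistic is undefined."""


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            # identical constants: no evidence of difference
            return 0.0, float(x.size + y.size - 2), 1.0
        raise UndefinedTestError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class EnrichmentResult:
    population: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_two_sided: float
    adjusted_p: float | None = None


def enrichment_table(
    abundance: np.ndarray,
    population_ids: list[str],
    sample_groups: list[str],
    group_a: str,
    adjust: str = "none",
) -> list[EnrichmentResult]:
    """Welch's test per population: ``group_a`` samples vs all others.

    ``abundance`` is populations x samples; ``sample_groups`` labels
    each column. ``adjust`` is ``"none"`` or ``"bh"`` (Benjamini-
    Hochberg step-up over all populations).
    """
    abundance = np.asarray(abundance, dtype=float)
    groups = np.asarray(sample_groups)
    mask_a = groups == group_a
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    rows = []
    for pid, values in zip(population_ids, abundance):
        a, b = values[mask_a], values[~mask_a]
        try:
            t, df, p = welch_t(a, b)
        except UndefinedTestError:
            t, df, p = float("nan"), float("nan"), float("nan")
        rows.append(
            EnrichmentResult(
                population=pid,
                group_a=group_a,
                group_b="rest",
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t_statistic=t,
                degrees_of_freedom=df,
                p_two_sided=p,
            )
        )
    if adjust == "bh":
        pvals = np.array([r.p_two_sided for r in rows])
        ok = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r.adjusted_p = None if np.isnan(q) else float(q)
    return rows
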