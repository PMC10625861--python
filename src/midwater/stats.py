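"""Nonparametric statistical battery used throughout the pipeline.

Kruskal–Wallis rank-sum test with tie correction, Dunn's post-hoc pairwise
comparisons with Bonferroni adjustment, ties-corrected Spearman rank
correlation, and the chi-square test of independence.  Kruskal–Wallis,
Spearman and chi-square delegate to SciPy, which implements exactly the
tie-corrected forms used here; Dunn's test is implemented directly from the
mean-rank z statistic with the pooled tie-correction term in its standard
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PairwiseResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman",
    "chi_square_independence",
]


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``df`` is an integer for chi-square-distributed statistics and a pair
    for F statistics.  ``degenerate`` flags inputs on which the test is
    vacuous (e.g. all observations identical).
    """

    statistic: float
    df: int | tuple[int, int]
    p: float
    groups: tuple[str, ...] = ()
    pairwise: tuple[PairwiseResult, ...] | None = None
    degenerate: bool = False


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = [str(g) for g in dict.fromkeys(groups)]  # first-appearance order
    samples = [values[groups == g] for g in dict.fromkeys(groups)]
    return labels, samples


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal–Wallis H with midrank ties and tie correction.

    H' = H / (1 − ΣT/(N³−N)) with T = t³ − t per tie group; p from the
    chi-square approximation on k − 1 degrees of freedom.  All observations
    identical is degenerate: H = 0, p = 1, flagged.
    """
    labels, samples = _split_groups(values, groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis: empty group")
    n_total = sum(len(s) for s in samples)
    if n_total < 3:
        raise ValueError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, len(labels) - 1, 1.0, tuple(labels), degenerate=True)
    stat, p = sps.kruskal(*samples)
    return TestResult(float(stat), len(labels) - 1, float(p), tuple(labels))


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> TestResult:
    """Dunn's post-hoc test for all group pairs after Kruskal–Wallis.

    For groups i, j with mean ranks R̄ᵢ, R̄ⱼ over the pooled midranks of N
    observations,

        z = (R̄ᵢ − R̄ⱼ) / sqrt( [N(N+1)/12 − ΣT/(12(N−1))] (1/nᵢ + 1/nⱼ) )

    where ΣT = Σ(t³ − t) pools all tie groups.  Two-sided normal p-values;
    Bonferroni multiplies by the number of pairs, capped at 1.
    """
    if adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    labels, samples = _split_groups(values, groups)
    if len(labels) < 2:
        raise ValueError("dunn_posthoc needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("dunn_posthoc: empty group")
    pooled = np.concatenate(samples)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    # pooled tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    variance_core = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    mean_ranks = {}
    start = 0
    for lab, s in zip(labels, samples):
        mean_ranks[lab] = float(ranks[start : start + len(s)].mean())
        start += len(s)
    sizes = dict(zip(labels, (len(s) for s in samples)))
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    m = len(pairs)
    results = []
    for a, b in pairs:
        se = np.sqrt(variance_core * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        results.append(PairwiseResult((a, b), float(z), p_raw, min(1.0, p_raw * m)))
    max_abs = max((abs(r.z) for r in results), default=0.0)
    min_p = min((r.p_adjusted for r in results), default=1.0)
    return TestResult(max_abs, len(labels) - 1, min_p, tuple(labels),
                      pairwise=tuple(results))


def spearman(x, y) -> tuple[float, float]:
    """Ties-corrected Spearman rank correlation with two-sided t-based p.

    rho is the Pearson correlation of midranks.  Raises on zero variance in
    either rank vector (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("spearman needs n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("spearman undefined: zero variance in midranks")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r × c count table.

    No continuity correction by default (the Yates correction only applies
    to 2 × 2 tables and is off unless requested).  Zero row or column
    margins are an error since expected counts are undefined.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    res = sps.chi2_contingency(table, correction=yates)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue))
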