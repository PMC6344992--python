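"""Shared statistical primitives.

The paired comparisons in this package (dendrite vs soma normalized counts,
per-cell change in distal fraction) act on small vectors of n <= 16 paired
differences, frequently containing ties and exact zeros.  The Wilcoxon
signed-rank test here therefore computes the *exact* null distribution of the
signed-rank sum under the tied rank configuration (zeros dropped, midranks),
via the shift algorithm over doubled midranks, rather than relying on a
normal approximation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_signed_rank",
    "bh_adjust",
    "fisher_2x2",
    "odds_ratio_2x2",
]


def _exact_signed_rank_pvalue(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for signed-rank sum ``w2`` given doubled midranks.

    ``ranks2`` are the midranks multiplied by 2 so they are integers even
    under ties.  Under the null each rank enters the positive sum
    independently with probability 1/2, so the distribution of the doubled
    positive rank sum W2 is the convolution of ``n`` two-point distributions
    {0, r}.  The distribution is symmetric about T/2 (T = sum of ranks); the
    two-sided p-value is P(|W2 - T/2| >= |w2 - T/2|).
    """
    ranks2 = np.asarray(ranks2, dtype=np.int64)
    total = int(ranks2.sum())
    # counts[s] = number of sign assignments with doubled rank sum s
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upper = 0
    for r in ranks2:
        counts[r : upper + r + 1] += counts[: upper + 1]
        upper += r
    counts /= counts.sum()
    dev = abs(w2 - total / 2.0)
    sums = np.arange(total + 1)
    # small epsilon guards float deviation comparisons on half-integer centers
    mask = np.abs(sums - total / 2.0) >= dev - 1e-9
    return float(min(1.0, counts[mask].sum()))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25):
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zeros are dropped (standard Wilcoxon convention), ties receive midranks.
    For n <= ``exact_max_n`` non-zero differences the exact conditional null
    distribution is used; beyond that a normal approximation with tie
    correction.

    Returns
    -------
    (statistic, pvalue, n_nonzero) : tuple
        ``statistic`` is the positive-rank sum W+; ``pvalue`` is two-sided.
        With no non-zero differences the test is degenerate and p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(ranks * 2).astype(np.int64)
        p = _exact_signed_rank_pvalue(ranks2, 2.0 * w_plus)
    else:
        total = ranks.sum()
        mu = total / 2.0
        var = np.sum(ranks**2) / 4.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return w_plus, p, n


def signed_rank_z(diffs) -> float:
    """Signed standardized Wilcoxon statistic (positive => positive shift).

    Used as a magnitude-of-evidence ordering key (e.g. somatic specificity
    when building background pools); not a p-value.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0
    ranks = _sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    sd = np.sqrt(np.sum(ranks**2) / 4.0)
    return float((w_plus - mu) / sd) if sd > 0 else 0.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN inputs propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (sample odds ratio, p).

    The odds ratio is the unconditional cross-product ratio ``ad/bc`` (the
    quantity quoted in enrichment reporting), with ``inf`` when bc == 0 and
    a*d > 0, and NaN for an all-degenerate table.
    """
    t = np.asarray(table, dtype=float)
    _, p = _sps.fisher_exact(t, alternative="two-sided")
    return odds_ratio_2x2(t), float(p)


def odds_ratio_2x2(table) -> float:
    (a, b), (c, d) = np.asarray(table, dtype=float)
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return float(num / den)
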