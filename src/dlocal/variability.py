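"""Per-gene dendritic read fractions and localization-variability statistics.

For one gene in one cell the dendritic read fraction is
f = d / (d + s), with d and s the dendritic and somatic read counts of that
cell.  Variability of localization across cells is the sample variance of f
over cells passing a minimum-total-reads filter.  A read-downsampling control
(all cells reduced to the same total, resampled binomially) separates genuine
localization variability from read-depth effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dendritic_fraction",
    "fraction_profile",
    "localization_variance",
    "downsampled_variance",
    "variability_table",
]


def dendritic_fraction(d: int, s: int) -> float:
    """d / (d + s); raises on a 0 + 0 cell (undefined, excluded upstream)."""
    if d < 0 or s < 0:
        raise ValueError("negative counts")
    if d + s == 0:
        raise ValueError("dendritic fraction undefined for d + s = 0")
    return d / (d + s)


def fraction_profile(dend, soma, min_total: int = 10) -> np.ndarray:
    """Per-cell fractions; cells with d + s < min_total are NaN."""
    d = np.asarray(dend, dtype=float)
    s = np.asarray(soma, dtype=float)
    tot = d + s
    f = np.full(d.shape, np.nan)
    ok = tot >= max(min_total, 1)
    f[ok] = d[ok] / tot[ok]
    return f


def localization_variance(dend, soma, min_total: int = 10) -> float:
    """Sample variance (ddof=1) of the dendritic read fraction across cells."""
    f = fraction_profile(dend, soma, min_total)
    f = f[~np.isnan(f)]
    if f.size < 2:
        return float("nan")
    return float(np.var(f, ddof=1))


def downsampled_variance(
    dend,
    soma,
    n_down: int = 10,
    reps: int = 1000,
    min_total: int | None = None,
    rng=None,
    ci: tuple[float, float] = (2.5, 97.5),
):
    """Read-depth-controlled localization variance.

    Every included cell (d + s >= n_down) is reduced to exactly ``n_down``
    reads by drawing Binomial(n_down, f_cell); the cross-cell sample variance
    of the resampled fractions is computed per replicate.  Returns
    (mean variance over reps, (ci_lo, ci_hi) nonparametric percentile CI).
    Deterministic for a fixed ``rng`` seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng)
    if min_total is None:
        min_total = n_down
    f = fraction_profile(dend, soma, max(min_total, n_down))
    f = f[~np.isnan(f)]
    if f.size < 2:
        return float("nan"), (float("nan"), float("nan"))
    draws = rng.binomial(n_down, f[None, :].repeat(reps, axis=0)) / n_down
    variances = draws.var(axis=1, ddof=1)
    lo, hi = np.percentile(variances, ci)
    return float(variances.mean()), (float(lo), float(hi))


def variability_table(
    gene_ids,
    dend_counts,
    soma_counts,
    min_total: int = 10,
    n_down: int = 10,
    reps: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Per-gene variability summary over a (genes x cells) pair of count arrays."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, d, s in zip(gene_ids, np.asarray(dend_counts), np.asarray(soma_counts)):
        f = fraction_profile(d, s, min_total)
        n_cells = int(np.sum(~np.isnan(f)))
        var = localization_variance(d, s, min_total)
        dmean, (lo, hi) = downsampled_variance(
            d, s, n_down=n_down, reps=reps, rng=rng
        )
        rows.append((g, n_cells, var, dmean, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_cells", "variance", "downsampled_mean", "ci_lo", "ci_hi"],
    ).set_index("gene_id")
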