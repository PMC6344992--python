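"""Length-matched non-localized backgrounds and the shared Fisher test.

Motif frequency scales with sequence length, so every enrichment test in
this package compares a localized foreground against a background of
non-localized (soma-higher) genes matched one-to-one on 3'UTR length:
scanning the pool in order of somatic specificity, the first pool gene
within ``tol`` (100 nt) of the foreground gene's length is taken and
removed; if none qualifies, the closest remaining length is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fisher_2x2


@dataclass
class EnrichmentResult:
    motif_id: str
    fg_genes_hit: int
    fg_genes_total: int
    bg_genes_hit: int
    bg_genes_total: int
    fold: float
    odds_ratio: float
    p: float


def build_pool(de_results: pd.DataFrame, exclude=(), stat_col: str = "stat"):
    """Ordered background pool: soma-higher genes minus exclusions.

    ``de_results`` is the call_de output (indexed by gene, with a ``call``
    column and a signed test statistic in ``stat_col``).  The pool is
    ordered by descending somatic specificity, i.e. ascending signed
    statistic (most negative first).
    """
    exclude = set(exclude)
    soma = de_results[de_results["call"] == "deSoma"]
    soma = soma[~soma.index.isin(exclude)]
    soma = soma.sort_values(stat_col, ascending=True, kind="stable")
    return list(soma.index)


def match_background(fg_lengths: dict, pool, pool_lengths: dict, tol: int = 100):
    """Greedy one-to-one length matching against an ordered pool.

    For each foreground gene (in iteration order) scan the pool in order and
    select the first gene within ``tol`` nt; fall back to the closest
    remaining length (ties broken by earlier pool position).  Selected genes
    are removed from the pool (sampling without replacement).

    Returns a DataFrame (fg_gene, bg_gene, fg_len, bg_len, within_tol).
    """
    if len(pool) < len(fg_lengths):
        raise ValueError(
            f"pool ({len(pool)}) smaller than foreground ({len(fg_lengths)})"
        )
    avail = list(pool)
    rows = []
    for fg, flen in fg_lengths.items():
        pick = None
        for i, bg in enumerate(avail):
            if abs(pool_lengths[bg] - flen) <= tol:
                pick = i
                break
        if pick is None:
            pick = min(
                range(len(avail)), key=lambda i: (abs(pool_lengths[avail[i]] - flen), i)
            )
        bg = avail.pop(pick)
        blen = pool_lengths[bg]
        rows.append((fg, bg, flen, blen, abs(blen - flen) <= tol))
    return pd.DataFrame(
        rows, columns=["fg_gene", "bg_gene", "fg_len", "bg_len", "within_tol"]
    )


def fisher_enrichment(
    fg_hits: int, fg_total: int, bg_hits: int, bg_total: int, motif_id: str = ""
) -> EnrichmentResult:
    """One-hit-per-gene Fisher enrichment of a motif in foreground vs background.

    fold = (fg_hits/fg_total) / (bg_hits/bg_total); two-sided Fisher exact p
    on the 2x2 table [[fg_hits, fg_total - fg_hits], [bg_hits, bg_total - bg_hits]].
    """
    if not (0 <= fg_hits <= fg_total and 0 <= bg_hits <= bg_total):
        raise ValueError("hits must lie in [0, total]")
    table = np.array(
        [[fg_hits, fg_total - fg_hits], [bg_hits, bg_total - bg_hits]]
    )
    orr, p = fisher_2x2(table)
    if bg_hits == 0 or fg_total == 0:
        fold = float("inf") if fg_hits > 0 else float("nan")
    else:
        fold = (fg_hits / fg_total) / (bg_hits / bg_total)
    return EnrichmentResult(
        motif_id, fg_hits, fg_total, bg_hits, bg_total, float(fold), orr, float(p)
    )


def enrichment_from_hits(fg_genes, bg_genes, genes_with_hit, motif_id: str = ""):
    """Count one hit per gene in each set and run the Fisher test."""
    fg = set(fg_genes)
    bg = set(bg_genes)
    hits = set(genes_with_hit)
    return fisher_enrichment(
        len(fg & hits), len(fg), len(bg & hits), len(bg), motif_id=motif_id
    )
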