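"""Cross-study integration of dendritic gene lists.

Published dendritic-transcriptome surveys overlap surprisingly little; a
ranked observation table (how many independent studies report each gene)
separates the recurrently observed core from single-study calls.  Symbols
are normalized to the mouse title-case convention; no alias or cross-species
ortholog mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)


def normalize_symbol(s: str) -> str:
    """Trim whitespace and map to mouse title case ('RPS29' -> 'Rps29')."""
    s = s.strip()
    if not s:
        return s
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class StudyGeneList:
    study_id: str
    genes: frozenset

    @classmethod
    def from_symbols(cls, study_id, symbols):
        norm = {normalize_symbol(x) for x in symbols}
        norm.discard("")
        return cls(study_id, frozenset(norm))

    @classmethod
    def from_tsv(cls, study_id, path, column: str = "gene"):
        df = pd.read_csv(path, sep="\t")
        col = column if column in df.columns else df.columns[0]
        return cls.from_symbols(study_id, df[col].astype(str))


def integrate(lists) -> pd.DataFrame:
    """Observation table over >= 2 study lists.

    Returns a DataFrame (symbol, n_obs, study_ids) ordered by n_obs
    descending then symbol; empty lists are excluded with a warning.
    Deterministic under permutation of the input order.
    """
    lists = [l for l in lists if l.genes or log.warning(
        "study %s contributed no genes; excluded", l.study_id) or False]
    if len(lists) < 2:
        raise ValueError("integrate requires at least two non-empty study lists")
    membership: dict[str, set] = {}
    for sl in lists:
        for g in sl.genes:
            membership.setdefault(g, set()).add(sl.study_id)
    rows = [
        (g, len(studies), ",".join(sorted(studies)))
        for g, studies in membership.items()
    ]
    df = pd.DataFrame(rows, columns=["symbol", "n_obs", "study_ids"])
    return df.sort_values(
        ["n_obs", "symbol"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
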