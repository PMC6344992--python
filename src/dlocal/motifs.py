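"""Linear cis-motif scanning: G-quadruplex regex and PWM log-odds search.

G-quadruplex candidates are four runs of >= 3 G separated by loops of 1-7
nt, found with the regular expression ``([gG]{3,}\\w{1,7}){3,}[gG]{3,}``
(non-overlapping, leftmost-greedy).  RBP binding sites are scored by
sliding-window log2-odds against a position weight matrix, with a per-motif
threshold proportional to its number of informative positions so that
longer, more specific motifs require a higher score to call a match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GQUAD_PATTERN = re.compile(r"([gG]{3,}\w{1,7}){3,}[gG]{3,}")

_BASES = "ACGU"
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    start: int
    end: int
    score: float | None = None


def find_gquadruplex(seq: str, gene_id: str = "", motif_id: str = "G4"):
    """Non-overlapping G-quadruplex pattern matches, left to right."""
    return [
        MotifHit(gene_id, motif_id, m.start(), m.end())
        for m in GQUAD_PATTERN.finditer(seq)
    ]


@dataclass
class Pwm:
    """Position weight matrix over A/C/G/U with a log-odds match threshold."""

    motif_id: str
    matrix: np.ndarray  # positions x 4 probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float = 0.0
    n_informative: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudo: float = 1e-9) -> np.ndarray:
        return np.log2((self.matrix + pseudo) / self.background[None, :])


def load_cisbp_pwm(path, motif_id=None) -> Pwm:
    """Read a CISBP-RNA-style tab-delimited PWM (Pos, A, C, G, U columns)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    try:
        mat = df[[cols["A"], cols["C"], cols["G"], cols.get("U", cols.get("T"))]]
    except KeyError as exc:
        raise ValueError(f"{path}: missing base column {exc}") from exc
    if motif_id is None:
        import os

        motif_id = os.path.splitext(os.path.basename(str(path)))[0]
    pwm = Pwm(motif_id, mat.to_numpy(dtype=float))
    pwm.threshold = pwm_threshold(pwm)
    return pwm


def information_content(pwm: Pwm) -> np.ndarray:
    """Per-position relative entropy (bits) of the PWM vs its background."""
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / pwm.background[None, :]), 0.0)
    return terms.sum(axis=1)


def pwm_threshold(pwm: Pwm, c: float = 1.0, ic_cut: float = 0.5) -> float:
    """Per-motif log-odds threshold: c x (number of positions with
    information content >= ic_cut bits)."""
    n_inf = int(np.sum(information_content(pwm) >= ic_cut))
    pwm.n_informative = n_inf
    return c * n_inf


def encode_rna(seq: str) -> np.ndarray:
    """A/C/G/U(T) -> 0..3; anything else (N, gaps) -> 4."""
    return np.array([_CODE.get(ch, 4) for ch in seq.upper()], dtype=np.int8)


def scan_pwm(seq: str, pwm: Pwm, gene_id: str = "", threshold=None):
    """All windows scoring >= threshold under the PWM log-odds model.

    Ambiguous bases (N) contribute 0 (background-equivalent); T and U are
    interchangeable.
    """
    if threshold is None:
        threshold = pwm.threshold
    w = pwm.width
    codes = encode_rna(seq)
    if codes.size < w:
        return []
    lo = pwm.log_odds()
    lo5 = np.hstack([lo, np.zeros((w, 1))])  # column 4: N scores 0
    # score all windows via strided indexing
    idx = np.arange(codes.size - w + 1)[:, None] + np.arange(w)[None, :]
    scores = lo5[np.arange(w)[None, :], codes[idx]].sum(axis=1)
    return [
        MotifHit(gene_id, pwm.motif_id, int(i), int(i + w), float(s))
        for i, s in zip(idx[:, 0], scores)
        if s >= threshold
    ]


def genes_with_motif(seqs: dict, scanner) -> set:
    """Apply a hit-list scanner to {gene: seq}; one hit per gene."""
    return {g for g, s in seqs.items() if scanner(s)}
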