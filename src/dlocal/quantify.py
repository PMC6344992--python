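"""Strand-specific read counting, normalization, and gene-level localization calls.

The paired design is central: each of the 16 cells contributes one soma and
one dendrite sample, and the differential caller tests the per-cell
(dendrite - soma) differences of size-factor-normalized counts with an exact
paired Wilcoxon signed-rank test followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats import bh_adjust, signed_rank_z, wilcoxon_signed_rank

log = logging.getLogger(__name__)

SOMA = "soma"
DENDRITE = "dendrite"


@dataclass
class PairedCountMatrix:
    """Per-feature counts over paired soma/dendrite samples.

    ``samples`` is a DataFrame with columns sample_id, cell_id, compartment
    (one row per column of ``counts``); every cell_id appears exactly once
    per compartment.
    """

    feature_ids: list[str]
    samples: pd.DataFrame
    counts: np.ndarray  # features x samples, integer >= 0
    feature_genes: dict[str, str] = field(default_factory=dict)
    size_factors: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.samples)):
            raise ValueError("counts shape does not match features x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        for comp, grp in self.samples.groupby("compartment"):
            if grp["cell_id"].duplicated().any():
                raise ValueError(f"duplicate cell_id within compartment {comp}")
        if not self.feature_genes:
            self.feature_genes = {f: f.split(":")[0] for f in self.feature_ids}

    @property
    def n_cells(self) -> int:
        return self.samples["cell_id"].nunique()

    def compartment_columns(self, compartment: str) -> np.ndarray:
        return np.flatnonzero((self.samples["compartment"] == compartment).to_numpy())

    def normalized(self) -> np.ndarray:
        if self.size_factors is None:
            raise ValueError("size factors not computed; call size_factors() first")
        return self.counts / self.size_factors[None, :]

    def paired_columns(self) -> tuple[np.ndarray, np.ndarray, list]:
        """Column indices of (dendrite, soma) samples matched by cell_id."""
        s = self.samples.reset_index(drop=True)
        piv = s.reset_index().pivot(index="cell_id", columns="compartment", values="index")
        piv = piv.dropna()
        cells = list(piv.index)
        return (
            piv[DENDRITE].to_numpy(dtype=int),
            piv[SOMA].to_numpy(dtype=int),
            cells,
        )

    def gene_level(self) -> "PairedCountMatrix":
        """Aggregate feature counts to gene level (sum over features)."""
        genes = sorted(set(self.feature_genes.values()))
        idx = {g: i for i, g in enumerate(genes)}
        agg = np.zeros((len(genes), self.counts.shape[1]), dtype=self.counts.dtype)
        for i, f in enumerate(self.feature_ids):
            agg[idx[self.feature_genes[f]]] += self.counts[i]
        return PairedCountMatrix(genes, self.samples.copy(), agg, {g: g for g in genes})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.samples["sample_id"]
        )


# ---------------------------------------------------------------------------
# counting

def count_reads(features, reads_by_sample, samples: pd.DataFrame) -> PairedCountMatrix:
    """Count strand-specific reads over non-overlapping features.

    A read counts toward a feature iff it overlaps it by >= 1 base on the
    same strand.  Reads overlapping features of more than one gene are
    discarded as ambiguous; within a gene the read is assigned to the single
    overlapped feature (ties broken by larger overlap, then by the more 3'
    feature in transcript orientation).

    Parameters
    ----------
    features : iterable of UtrFeature
    reads_by_sample : mapping sample_id -> iterable of (chrom, start, end, strand)
    samples : DataFrame with sample_id / cell_id / compartment columns
    """
    features = list(features)
    trees: dict[tuple[str, str], IntervalTree] = {}
    chroms = set()
    for fi, f in enumerate(features):
        chroms.add(f.chrom)
        t = trees.setdefault((f.chrom, f.strand), IntervalTree())
        for s, e in f.intervals:
            t[s:e] = fi

    fid = [f.feature_id for f in features]
    counts = np.zeros((len(features), len(samples)), dtype=np.int64)
    missing_chroms = set()
    for col, sid in enumerate(samples["sample_id"]):
        for chrom, start, end, strand in reads_by_sample.get(sid, ()):
            if chrom not in chroms:
                if chrom not in missing_chroms:
                    missing_chroms.add(chrom)
                    log.warning("chromosome %s absent from annotation; reads skipped", chrom)
                continue
            tree = trees.get((chrom, strand))
            if tree is None:
                continue
            hits = tree[start:end]
            if not hits:
                continue
            genes = {features[h.data].gene_id for h in hits}
            if len(genes) > 1:
                continue  # ambiguous between genes
            best = None
            for h in hits:
                f = features[h.data]
                ov = sum(
                    max(0, min(end, e) - max(start, s)) for s, e in f.intervals
                )
                # tie-break key: overlap, then more 3' in transcript orientation
                three_prime = f.end if f.strand == "+" else -f.start
                key = (ov, three_prime)
                if best is None or key > best[0]:
                    best = (key, h.data)
            counts[best[1], col] += 1
    return PairedCountMatrix(
        fid, samples.reset_index(drop=True), counts,
        {f.feature_id: f.gene_id for f in features},
    )


def load_read_bed(path):
    """Read one interval per uniquely mapped read/fragment from BED6."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            out.append((p[0], int(p[1]), int(p[2]), p[5].strip()))
    return out


# ---------------------------------------------------------------------------
# normalization and filters

def size_factors(m: PairedCountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq2 estimator).

    s_j = median over features i (with all-positive counts) of
    K_ij / geometric-mean_j'(K_ij').  Falls back to total-count ratios
    (scaled to geometric mean 1) when no feature is positive in every
    sample, with a warning.
    """
    K = np.asarray(m.counts, dtype=float)
    allpos = (K > 0).all(axis=1)
    if allpos.any():
        logK = np.log(K[allpos])
        loggeo = logK.mean(axis=1, keepdims=True)
        s = np.exp(np.median(logK - loggeo, axis=0))
    else:
        log.warning("no feature positive in all samples; using total-count ratios")
        tot = K.sum(axis=0)
        if (tot == 0).any():
            raise ValueError("sample with zero total counts")
        s = tot / np.exp(np.mean(np.log(tot)))
    m.size_factors = s
    return s


def filter_expressed(m: PairedCountMatrix, min_reads: int = 1, min_samples: int = 16):
    """Features with >= min_reads in >= min_samples samples (raw counts)."""
    ok = (m.counts >= min_reads).sum(axis=1) >= min_samples
    return {m.feature_ids[i] for i in np.flatnonzero(ok)}


# ---------------------------------------------------------------------------
# localization calls

def call_de(
    m: PairedCountMatrix,
    genes=None,
    alpha_fdr: float = 0.05,
    min_pairs: int = 6,
) -> pd.DataFrame:
    """Paired dendrite-vs-soma differential test per gene.

    For each gene, the per-cell differences of normalized counts
    (dendrite - soma) are tested with an exact two-sided Wilcoxon
    signed-rank test; BH correction is applied over the tested genes only.
    ``deDend`` requires q <= alpha_fdr and median difference > 0 (``deSoma``
    symmetric).  Genes with fewer than ``min_pairs`` complete pairs are
    marked untestable.

    Returns a DataFrame indexed by gene with columns
    n_pairs / median_diff / stat / p / q / call.
    """
    if m.size_factors is None:
        size_factors(m)
    norm = m.normalized()
    dcols, scols, _cells = m.paired_columns()
    ids = m.feature_ids
    rows = np.arange(len(ids)) if genes is None else [
        ids.index(g) for g in genes
    ]
    rec = []
    for i in rows:
        diff = norm[i, dcols] - norm[i, scols]
        diff = diff[~np.isnan(diff)]
        if diff.size < min_pairs:
            rec.append((ids[i], diff.size, np.nan, np.nan, np.nan))
            continue
        _, p, _ = wilcoxon_signed_rank(diff)
        rec.append((ids[i], diff.size, float(np.median(diff)), signed_rank_z(diff), p))
    df = pd.DataFrame(rec, columns=["gene_id", "n_pairs", "median_diff", "stat", "p"])
    df["q"] = bh_adjust(df["p"])
    call = np.full(len(df), "none", dtype=object)
    call[df["p"].isna().to_numpy()] = "untestable"
    sig = (df["q"] <= alpha_fdr).to_numpy() & df["p"].notna().to_numpy()
    call[sig & (df["median_diff"] > 0).to_numpy()] = "deDend"
    call[sig & (df["median_diff"] < 0).to_numpy()] = "deSoma"
    df["call"] = call
    return df.set_index("gene_id")


def call_consdend(m: PairedCountMatrix, genes=None, min_fraction: float = 0.90,
                  min_reads: int = 1):
    """Genes with >= min_reads in >= ceil(min_fraction * n_dendrite) dendrite samples."""
    dcols = m.compartment_columns(DENDRITE)
    need = int(np.ceil(min_fraction * len(dcols)))
    detected = (m.counts[:, dcols] >= min_reads).sum(axis=1)
    out = {
        m.feature_ids[i]
        for i in np.flatnonzero(detected >= need)
    }
    if genes is not None:
        out &= set(genes)
    return out
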