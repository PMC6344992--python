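"""Synthetic paired soma/dendrite data with known ground truth.

Emulates the study design this package analyzes: 16 cells, each
contributing one soma and one dendrite sample; genes carry 1-4 alternative
3' isoforms; counts are negative-binomial with gene-level dispersion,
whole-gene dropout, and per-sample library-size factors.  Four planted gene
classes drive every pipeline stage:

* ``dedend``     - concentration-enriched in dendrites (ratio >> 1);
* ``consdend``   - constitutively detected in dendrites but not enriched;
* ``isodend``    - one 3' isoform consistently preferred in dendrites
                   (distal-fraction shift of +/- ``delta_df`` per cell);
* ``nonloc``     - no localization signal.

All draws flow from one ``numpy`` Generator; a fixed seed gives
bit-identical annotation, counts, and sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, Transcript, build_isoform_windows, build_union_utr
from .quantify import DENDRITE, SOMA, PairedCountMatrix

DEDEND, CONSDEND, ISODEND, NONLOC = "dedend", "consdend", "isodend", "nonloc"


@dataclass
class SimScenario:
    """Generating parameters; defaults are the package's reference conditions."""

    n_cells: int = 16
    n_genes: int = 1000
    frac_dedend: float = 0.05
    frac_consdend: float = 0.15
    frac_isodend: float = 0.10
    dedend_ratio: float = 10.0  # dendrite/soma concentration for dedend genes
    baseline_dend_ratio: float = 0.5  # dendrites capture fewer reads overall
    delta_df: float = 0.3  # per-cell DF shift for isodend genes
    distal_pref_frac: float = 0.64  # fraction of isodend genes shifted toward distal
    iso_count_probs: tuple = (0.35, 0.40, 0.17, 0.08)  # P(1..4 isoforms)
    nb_dispersion: float = 0.3
    dropout: float = 0.05  # whole-gene-per-sample dropout probability
    libsize_sigma: float = 0.3
    mean_log: float = 5.0  # soma baseline: lognormal(mean_log, sd_log) reads
    sd_log: float = 1.0
    ale_fraction: float = 0.85
    merge_rate: float = 0.10  # genes given an extra 3' end < 500 nt from the distal end
    utr_len_meanlog: float = 6.2
    utr_len_sdlog: float = 0.6
    base_probs: tuple = (0.3, 0.2, 0.2, 0.3)  # A, C, G, T for background sequence

    def __post_init__(self):
        if self.frac_dedend + self.frac_consdend + self.frac_isodend > 1:
            raise ValueError("class fractions must sum to <= 1")
        if not 0 < self.delta_df <= 1:
            raise ValueError("delta_df must be in (0, 1]")
        if abs(sum(self.iso_count_probs) - 1) > 1e-9:
            raise ValueError("iso_count_probs must sum to 1")


@dataclass(frozen=True)
class MotifSpec:
    """A motif instance planted into localized vs background 3'UTRs."""

    motif_id: str
    instance: str
    fg_rate: float
    bg_rate: float = 0.0


class StudyBundle(NamedTuple):
    plan: pd.DataFrame
    gene_models: list
    features: list  # isoform_window features, all genes
    union_features: list
    matrix: PairedCountMatrix  # isoform-window counts
    truth: pd.DataFrame


def plan_genes(sc: SimScenario, seed) -> pd.DataFrame:
    """Per-gene generating parameters (the ground-truth table).

    Class labels are assigned in deterministic blocks; stochastic per-gene
    parameters (baseline expression, isoform counts, geometry, DF values)
    come from the seeded generator so that annotation, counts, and sequences
    built from the same plan agree.
    """
    rng = np.random.default_rng(seed)
    n = sc.n_genes
    n_de = round(sc.frac_dedend * n)
    n_cons = round(sc.frac_consdend * n)
    n_iso = round(sc.frac_isodend * n)
    cls = np.array(
        [DEDEND] * n_de + [CONSDEND] * n_cons + [ISODEND] * n_iso
        + [NONLOC] * (n - n_de - n_cons - n_iso)
    )
    n_isoforms = rng.choice(
        np.arange(1, len(sc.iso_count_probs) + 1), size=n, p=sc.iso_count_probs
    )
    n_isoforms[cls == ISODEND] = np.maximum(n_isoforms[cls == ISODEND], 2)

    base_soma = rng.lognormal(sc.mean_log, sc.sd_log, size=n)
    base_soma[cls == CONSDEND] = np.maximum(base_soma[cls == CONSDEND], 150.0)
    base_soma[cls == ISODEND] = np.maximum(base_soma[cls == ISODEND], 60.0)
    dend_ratio = np.full(n, sc.baseline_dend_ratio)
    dend_ratio[cls == DEDEND] *= sc.dedend_ratio

    tandem = rng.random(n) >= sc.ale_fraction
    merged_end = rng.random(n) < sc.merge_rate

    df_soma = np.full(n, np.nan)
    df_dend = np.full(n, np.nan)
    sign = np.zeros(n)
    multi = n_isoforms >= 2
    iso_mask = cls == ISODEND
    df_soma[iso_mask] = rng.uniform(0.30, 0.50, iso_mask.sum())
    sign[iso_mask] = np.where(
        rng.random(iso_mask.sum()) < sc.distal_pref_frac, 1.0, -1.0
    )
    df_dend[iso_mask] = np.clip(
        df_soma[iso_mask] + sign[iso_mask] * sc.delta_df, 0.02, 0.98
    )
    other_multi = multi & ~iso_mask
    df_soma[other_multi] = rng.uniform(0.2, 0.8, other_multi.sum())
    df_dend[other_multi] = df_soma[other_multi]

    utr_len = np.clip(
        rng.lognormal(sc.utr_len_meanlog, sc.utr_len_sdlog, size=(n, 4)), 150, 3000
    ).astype(int)
    gap = rng.integers(600, 2500, size=(n, 4))
    gap[merged_end] = np.maximum(gap[merged_end], 900)

    return pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "cls": cls,
            "n_isoforms": n_isoforms,
            "base_soma": base_soma,
            "dend_ratio": dend_ratio,
            "tandem": tandem,
            "merged_end": merged_end,
            "df_soma": df_soma,
            "df_dendrite": df_dend,
            "sign": sign,
            "utr_len1": utr_len[:, 0],
            "utr_len2": utr_len[:, 1],
            "utr_len3": utr_len[:, 2],
            "utr_len4": utr_len[:, 3],
            "gap1": gap[:, 0],
            "gap2": gap[:, 1],
            "gap3": gap[:, 2],
        }
    ).set_index("gene_id")


def simulate_annotation(sc: SimScenario, seed=None, plan=None) -> list[GeneModel]:
    """Gene models realizing the planned isoform geometry on one chromosome.

    Isoform pair 1-2 is tandem (overlapping full-length UTRs) or ALE
    (disjoint last exons) per plan; further isoforms extend ALE-style.
    ``merged_end`` genes carry an extra transcript whose 3' end lies 300 nt
    upstream of the distal end, exercising the < 500 nt merge rule without
    changing the feature count.
    """
    if plan is None:
        plan = plan_genes(sc, seed)
    genes = []
    cursor = 1000
    for gene_id, r in plan.iterrows():
        k = int(r["n_isoforms"])
        txs = []
        x = cursor
        lens = [int(r[f"utr_len{i}"]) for i in range(1, 5)]
        gaps = [int(r[f"gap{i}"]) for i in range(1, 4)]
        ends = []
        if r["tandem"] and k >= 2:
            # isoform 2 shares the UTR start and reads through
            e1 = x + lens[0]
            ends = [e1, e1 + gaps[0]]
            txs.append(Transcript(f"{gene_id}.t1", ((x, e1),), e1))
            txs.append(Transcript(f"{gene_id}.t2", ((x, ends[1]),), ends[1]))
            right = ends[1]
            for i in range(2, k):
                s = right + gaps[i - 1]
                e = s + lens[i]
                txs.append(Transcript(f"{gene_id}.t{i+1}", ((s, e),), e))
                ends.append(e)
                right = e
        else:
            right = x
            for i in range(k):
                s = right + (gaps[i - 1] if i else 0)
                e = s + lens[i]
                txs.append(Transcript(f"{gene_id}.t{i+1}", ((s, e),), e))
                ends.append(e)
                right = e
        if r["merged_end"] and k >= 2:
            # extra 3' end 300 nt upstream of the distal end, same last exon
            tx = txs[-1]
            e_extra = tx.end3 - 300
            s0 = tx.utr3_intervals[0][0]
            if e_extra > s0:
                txs.append(
                    Transcript(f"{gene_id}.tx", ((s0, e_extra),), e_extra)
                )
        genes.append(GeneModel(gene_id, "chrS", "+", txs))
        cursor = max(t.utr3_intervals[-1][1] for t in txs) + 5000
    return genes


def _isoform_fractions(sc, plan, rng):
    """Per-gene per-isoform read fractions for soma and dendrite."""
    frac_s, frac_d = {}, {}
    for gene_id, r in plan.iterrows():
        k = int(r["n_isoforms"])
        if k == 1:
            frac_s[gene_id] = frac_d[gene_id] = np.ones(1)
            continue
        rest = 0.1 if k > 2 else 0.0
        w_pair = 1.0 - rest
        other = np.full(k - 2, rest / (k - 2)) if k > 2 else np.empty(0)
        fs = np.concatenate(
            [[w_pair * (1 - r["df_soma"]), w_pair * r["df_soma"]], other]
        )
        fd = np.concatenate(
            [[w_pair * (1 - r["df_dendrite"]), w_pair * r["df_dendrite"]], other]
        )
        frac_s[gene_id], frac_d[gene_id] = fs, fd
    return frac_s, frac_d


def simulate_counts(sc: SimScenario, seed=None, plan=None):
    """Isoform-window count matrix over 16 paired samples, plus ground truth.

    Per gene and sample: mean = baseline x compartment ratio x isoform
    fraction x library factor; counts ~ NB(mean, dispersion); the whole gene
    drops out of a sample with probability ``dropout``.
    """
    if plan is None:
        plan = plan_genes(sc, seed)
        rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    else:
        rng = np.random.default_rng(seed)
    cells = [f"c{i:02d}" for i in range(sc.n_cells)]
    samples = pd.DataFrame(
        [
            (f"{c}_{comp}", c, comp)
            for c in cells
            for comp in (SOMA, DENDRITE)
        ],
        columns=["sample_id", "cell_id", "compartment"],
    )
    lib = rng.lognormal(0.0, sc.libsize_sigma, size=len(samples))
    frac_s, frac_d = _isoform_fractions(sc, plan, rng)

    feature_ids, feature_genes, rows = [], {}, []
    r_nb = 1.0 / sc.nb_dispersion
    is_dend = (samples["compartment"] == DENDRITE).to_numpy()
    for gene_id, r in plan.iterrows():
        k = int(r["n_isoforms"])
        # consdend genes are constitutively present by definition: no dropout
        p_drop = 0.0 if r["cls"] == CONSDEND else sc.dropout
        drop = rng.random((len(samples),)) < p_drop
        comp_mean = r["base_soma"] * np.where(is_dend, r["dend_ratio"], 1.0)
        for iso in range(k):
            fid = f"{gene_id}:iso{iso + 1}"
            feature_ids.append(fid)
            feature_genes[fid] = gene_id
            f = np.where(is_dend, frac_d[gene_id][iso], frac_s[gene_id][iso])
            mu = comp_mean * f * lib
            counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
            counts[drop] = 0
            rows.append(counts)
    counts = np.vstack(rows)
    m = PairedCountMatrix(feature_ids, samples, counts, feature_genes)
    truth = plan[["cls", "n_isoforms", "df_soma", "df_dendrite", "sign", "tandem"]].copy()
    truth["proximal_id"] = [f"{g}:iso1" for g in plan.index]
    truth["distal_id"] = [
        f"{g}:iso2" if k >= 2 else "" for g, k in zip(plan.index, plan["n_isoforms"])
    ]
    return m, truth


_B = np.array(list("ACGT"))


def simulate_sequences(sc: SimScenario, specs=(), seed=None, plan=None):
    """Random-background 3'UTR sequences with planted motif instances.

    Localized genes (plan class != nonloc) receive each spec's instance with
    probability ``fg_rate``; non-localized genes with ``bg_rate``.  Planting
    replaces a same-length slice at a random position, keeping lengths
    fixed.  Returns ({gene: seq}, DataFrame of planted positions).
    """
    if plan is None:
        plan = plan_genes(sc, seed)
        rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31) + 1)
    else:
        rng = np.random.default_rng(seed)
    seqs, planted = {}, []
    p = np.asarray(sc.base_probs, dtype=float)
    p = p / p.sum()
    for gene_id, r in plan.iterrows():
        length = int(sum(r[f"utr_len{i}"] for i in range(1, int(r["n_isoforms"]) + 1)))
        seq = "".join(rng.choice(_B, size=length, p=p))
        fg = r["cls"] != NONLOC
        for spec in specs:
            rate = spec.fg_rate if fg else spec.bg_rate
            inst = spec.instance
            if len(inst) + 2 > length or rng.random() >= rate:
                continue
            pos = int(rng.integers(0, length - len(inst) + 1))
            seq = seq[:pos] + inst + seq[pos + len(inst):]
            planted.append((gene_id, spec.motif_id, pos, pos + len(inst)))
        seqs[gene_id] = seq
    truth = pd.DataFrame(planted, columns=["gene_id", "motif_id", "start", "end"])
    return seqs, truth


def simulate_study(sc: SimScenario, seed) -> StudyBundle:
    """Plan + annotation + features + counts for one synthetic study."""
    plan = plan_genes(sc, seed)
    sub = np.random.default_rng(seed)
    gene_models = simulate_annotation(sc, plan=plan)
    features = []
    union_features = []
    for g in gene_models:
        features.extend(build_isoform_windows(g))
        union_features.append(build_union_utr(g))
    matrix, truth = simulate_counts(sc, seed=int(sub.integers(2**31)), plan=plan)
    return StudyBundle(plan, gene_models, features, union_features, matrix, truth)
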