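"""Isoform-level dendritic localization via the distal-fraction statistic.

For each multi-3'UTR gene the two most highly expressed 3' isoforms are
selected; the more 5' is "proximal", the more 3' "distal".  Per sample,
DF = distal / (distal + proximal) reads (undefined below a minimum read
total), and per cell dDF = DF_dendrite - DF_soma.  A gene is isoDend when
dDF keeps a consistent sign across cells: exact paired Wilcoxon signed-rank
p < 0.1 over at least five valid soma/dendrite pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import fisher_2x2, wilcoxon_signed_rank

DISTAL = "distal"
PROXIMAL = "proximal"


def select_top_two(iso_counts: pd.DataFrame, min_reads: int = 10):
    """Top two isoforms of one gene by summed per-sample read fractions.

    ``iso_counts``: isoform features (rows, ordered 5' -> 3' in transcript
    orientation) x samples.  Samples with fewer than ``min_reads`` total
    reads for the gene are skipped.  Ties in summed fraction are broken by
    larger total raw reads, then by the more distal feature.

    Returns (proximal_id, distal_id), or None if no sample qualifies.
    """
    if iso_counts.shape[0] < 2:
        raise ValueError("select_top_two needs >= 2 isoform features")
    K = iso_counts.to_numpy(dtype=float)
    tot = K.sum(axis=0)
    ok = tot >= min_reads
    if not ok.any():
        return None
    frac_sum = (K[:, ok] / tot[ok][None, :]).sum(axis=1)
    raw = K.sum(axis=1)
    order = np.arange(K.shape[0])  # row position == 5'->3' order
    # sort descending by (frac_sum, raw reads, distality)
    key = sorted(range(K.shape[0]), key=lambda i: (-frac_sum[i], -raw[i], -order[i]))
    top = sorted(key[:2])  # back to 5'->3' order
    ids = list(iso_counts.index)
    return ids[top[0]], ids[top[1]]


def distal_fraction(distal_reads, proximal_reads, min_reads: int = 10) -> float:
    """DF = distal / (distal + proximal); NaN when the total is < min_reads."""
    tot = distal_reads + proximal_reads
    if tot < min_reads:
        return float("nan")
    return float(distal_reads / tot)


def test_isoform_localization(delta_df, min_pairs: int = 5, alpha: float = 0.1):
    """isoDend call from the per-cell dDF vector.

    Returns (p, n_valid, isodend, preferred).  ``preferred`` is distal for
    median dDF > 0, proximal for < 0 (median 0 broken by the mean); for an
    untestable or insignificant gene it still reports the mean-sign
    preference used by the cohort background construction.
    """
    d = np.asarray(delta_df, dtype=float)
    d = d[~np.isnan(d)]
    n_valid = d.size
    if n_valid == 0:
        return float("nan"), 0, False, None
    med, mean = float(np.median(d)), float(np.mean(d))
    if n_valid < min_pairs:
        return float("nan"), n_valid, False, _sign_pref(mean)
    _, p, _ = wilcoxon_signed_rank(d)
    isodend = p < alpha
    pref = _sign_pref(med) if med != 0 else _sign_pref(mean)
    if not isodend:
        pref = _sign_pref(mean)
    return p, n_valid, isodend, pref


# the function is named for the operation it performs, not a test case
test_isoform_localization.__test__ = False


def _sign_pref(x):
    if x > 0:
        return DISTAL
    if x < 0:
        return PROXIMAL
    return None


@dataclass
class IsoformAnalysis:
    """Per-gene records plus the per-sample DF profiles backing them."""

    records: pd.DataFrame  # indexed by gene_id
    df_soma: dict  # gene_id -> per-cell soma DF (NaN where undefined)
    df_dendrite: dict


def analyze_isoforms(
    m,
    features,
    gene_models=None,
    min_reads: int = 10,
    min_pairs: int = 5,
    alpha: float = 0.1,
) -> IsoformAnalysis:
    """Run the full per-gene isoform localization analysis.

    ``m`` is a PairedCountMatrix over isoform_window features; ``features``
    the corresponding UtrFeature list (supplies 5'->3' order and ALE/tandem
    geometry via ``gene_models`` when given).  Genes with a single isoform
    feature are excluded; genes whose dDF vector has fewer than
    ``min_pairs`` valid cells are reported as untested (p = NaN).
    """
    from .annotation import classify_gene_pair

    feat_by_gene: dict[str, list] = {}
    for f in features:
        feat_by_gene.setdefault(f.gene_id, []).append(f)
    frame = m.to_frame()
    dcols, scols, cells = m.paired_columns()
    sample_ids = m.samples["sample_id"].to_numpy()
    gm_by_id = {g.gene_id: g for g in (gene_models or [])}

    rows, df_soma, df_dend = [], {}, {}
    for gene_id in sorted(feat_by_gene):
        feats = feat_by_gene[gene_id]
        if len(feats) < 2:
            continue
        # rows already follow construction order iso1..isoK == 5'->3'
        ids = [f.feature_id for f in feats]
        sub = frame.loc[ids]
        top = select_top_two(sub, min_reads=min_reads)
        if top is None:
            continue
        prox_id, dist_id = top
        dvec = sub.loc[dist_id].to_numpy(dtype=float)
        pvec = sub.loc[prox_id].to_numpy(dtype=float)
        df_all = np.array(
            [distal_fraction(d, p, min_reads) for d, p in zip(dvec, pvec)]
        )
        by_sample = dict(zip(sample_ids, df_all))
        fs = np.array([by_sample[sample_ids[i]] for i in scols])
        fd = np.array([by_sample[sample_ids[i]] for i in dcols])
        delta = fd - fs  # NaN unless both defined
        p, n_valid, isodend, pref = test_isoform_localization(
            delta, min_pairs=min_pairs, alpha=alpha
        )
        cls = None
        gm = gm_by_id.get(gene_id)
        if gm is not None:
            fmap = {f.feature_id: f for f in feats}
            cls = classify_gene_pair(gm, fmap[prox_id], fmap[dist_id]).cls
        var_s = float(np.nanvar(fs, ddof=1)) if np.sum(~np.isnan(fs)) > 1 else np.nan
        var_d = float(np.nanvar(fd, ddof=1)) if np.sum(~np.isnan(fd)) > 1 else np.nan
        rows.append(
            (gene_id, prox_id, dist_id, cls, n_valid, p, isodend, pref,
             float(np.nanmean(delta)) if n_valid else np.nan,
             float(np.nanmedian(delta)) if n_valid else np.nan,
             var_s, var_d)
        )
        df_soma[gene_id] = fs
        df_dend[gene_id] = fd

    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "proximal", "distal", "cls", "n_pairs", "p", "isodend",
            "preferred", "mean_delta", "median_delta",
            "df_var_soma", "df_var_dendrite",
        ],
    ).set_index("gene_id")
    return IsoformAnalysis(records, df_soma, df_dend)


def tested_mask(records: pd.DataFrame) -> pd.Series:
    return records["p"].notna()


def preference_summary(records: pd.DataFrame):
    """Distal-vs-proximal preference enrichment of isoDend genes.

    2x2 table of distal/proximal preference in isoDend genes vs the
    remaining tested genes (complement), where a non-isoDend gene's
    preference is the sign of its mean dDF.  Returns
    {"table", "odds_ratio", "p", "frac_isodend_distal", "frac_tested_distal"}.
    """
    tested = records[tested_mask(records)]
    iso = tested[tested["isodend"]]
    rest = tested[~tested["isodend"]]

    def _counts(df):
        return (
            int((df["preferred"] == DISTAL).sum()),
            int((df["preferred"] == PROXIMAL).sum()),
        )

    a, b = _counts(iso)
    c, d = _counts(rest)
    table = np.array([[a, b], [c, d]])
    orr, p = fisher_2x2(table)
    n_iso, n_tested = len(iso), len(tested)
    return {
        "table": table,
        "odds_ratio": orr,
        "p": p,
        "frac_isodend_distal": a / n_iso if n_iso else float("nan"),
        "frac_tested_distal": (a + c) / n_tested if n_tested else float("nan"),
    }


def df_variance_comparison(
    analysis: IsoformAnalysis,
    n_down: int = 10,
    reps: int = 1000,
    seed=None,
):
    """Soma-vs-dendrite DF variability, with a soma read-depth control.

    Raw comparison: per tested gene, is the cross-sample variance of DF
    larger in the soma than in the dendrites?  Cohort test: 2x2 Fisher of
    soma-more-variable counts in the isoDend genes vs the full tested set.
    Control: soma DFs are resampled at ``n_down`` reads
    (Binomial(n_down, DF)) per replicate and the isoDend soma-more-variable
    fraction re-measured; the mean over replicates is reported.
    """
    rng = np.random.default_rng(seed)
    rec = records = analysis.records[tested_mask(analysis.records)]
    genes = list(rec.index)
    smv = (rec["df_var_soma"] > rec["df_var_dendrite"])
    iso = rec["isodend"].to_numpy()
    a = int(smv[iso].sum()); b = int((~smv[iso]).sum())
    c = int(smv.sum()); d = int((~smv).sum())
    table = np.array([[a, b], [c, d]])
    orr, p = fisher_2x2(table)

    iso_genes = [g for g, flag in zip(genes, iso) if flag]
    fracs = np.empty(reps)
    for r in range(reps):
        n_more = 0
        n_tot = 0
        for g in iso_genes:
            fs = analysis.df_soma[g]
            ok = ~np.isnan(fs)
            if ok.sum() < 2:
                continue
            res = rng.binomial(n_down, fs[ok]) / n_down
            var_s = res.var(ddof=1)
            var_d = records.loc[g, "df_var_dendrite"]
            if np.isnan(var_d):
                continue
            n_tot += 1
            n_more += var_s > var_d
        fracs[r] = n_more / n_tot if n_tot else np.nan
    return {
        "per_gene_soma_more_variable": pd.Series(smv.to_numpy(), index=genes),
        "table": table,
        "odds_ratio": orr,
        "p": p,
        "frac_isodend_soma_more_variable": a / max(a + b, 1),
        "frac_tested_soma_more_variable": c / max(c + d, 1),
        "downsampled_mean_fraction": float(np.nanmean(fracs)),
    }


def length_comparison(records: pd.DataFrame, utr_lengths) -> pd.DataFrame:
    """Paired t-test: dendrite-preferred vs non-preferred full-length 3'UTR
    length among isoDend genes, separately for ALE and tandem pairs.

    ``utr_lengths`` maps feature_id -> full-length 3'UTR length.
    """
    iso = records[records["isodend"] & records["preferred"].notna()]
    out = []
    for cls, grp in iso.groupby("cls"):
        pref_len, other_len = [], []
        for _, r in grp.iterrows():
            pref = r["distal"] if r["preferred"] == DISTAL else r["proximal"]
            other = r["proximal"] if r["preferred"] == DISTAL else r["distal"]
            if pref in utr_lengths and other in utr_lengths:
                pref_len.append(utr_lengths[pref])
                other_len.append(utr_lengths[other])
        n = len(pref_len)
        if n < 2:
            out.append((cls, n, np.nan, np.nan, np.nan))
            continue
        diffs = np.asarray(pref_len, float) - np.asarray(other_len, float)
        if np.allclose(diffs.std(ddof=1), 0):
            t, p = (0.0, 1.0) if np.allclose(diffs, 0) else (np.inf, 0.0)
        else:
            t, p = _sps.ttest_rel(pref_len, other_len)
        out.append((cls, n, float(diffs.mean()), float(t), float(p)))
    return pd.DataFrame(
        out, columns=["cls", "n", "mean_diff", "t", "p"]
    ).set_index("cls")
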