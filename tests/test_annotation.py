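"""Union-3'UTR / isoform-window construction and ALE-tandem classification."""

import numpy as np
import pytest

from dlocal.annotation import (
    ALE,
    TANDEM,
    GeneModel,
    Transcript,
    build_isoform_windows,
    build_union_utr,
    classify_pair,
    load_gene_models,
    merge_intervals,
)
from dlocal.simulate import SimScenario, simulate_annotation


def gene(strand="+", utrs=None, gene_id="gX"):
    txs = []
    for i, ivs in enumerate(utrs, 1):
        ivs = tuple(ivs)
        end3 = max(e for _, e in ivs) if strand == "+" else min(s for s, _ in ivs)
        txs.append(Transcript(f"{gene_id}.t{i}", ivs, end3))
    return GeneModel(gene_id, "chr1", strand, txs)


class TestUnionUtr:
    def test_single_transcript_identity(self):
        f = build_union_utr(gene(utrs=[[(100, 600)]]))
        assert f.intervals == ((100, 600),)
        assert f.kind == "union_utr"

    def test_overlapping_utrs_merge(self):
        # brute-force base-set union of [100,600) and [400,900) is [100,900)
        f = build_union_utr(gene(utrs=[[(100, 600)], [(400, 900)]]))
        assert f.intervals == ((100, 900),)
        base_set = set(range(100, 600)) | set(range(400, 900))
        assert f.length == len(base_set)

    def test_disjoint_utrs_stay_separate(self):
        f = build_union_utr(gene(utrs=[[(100, 600)], [(2000, 2500)]]))
        assert f.intervals == ((100, 600), (2000, 2500))
        assert f.length == 1000

    def test_length_bounds_on_random_genes(self):
        genes = simulate_annotation(SimScenario(n_genes=40), seed=3)
        for g in genes:
            f = build_union_utr(g)
            per_tx = [sum(e - s for s, e in t.utr3_intervals) for t in g.transcripts]
            assert max(per_tx) <= f.length <= sum(per_tx)


class TestIsoformWindows:
    def test_close_ends_merge_into_one_feature(self):
        g = gene(utrs=[[(0, 1000)], [(0, 1300)]])
        feats = build_isoform_windows(g)  # ends 1000 and 1300, 300 nt apart
        assert len(feats) == 1
        assert feats[0].member_end3s == (1000, 1300)

    def test_distant_ends_give_two_windows(self):
        g = gene(utrs=[[(0, 1000)], [(0, 1800)]])
        feats = build_isoform_windows(g)
        assert [f.intervals for f in feats] == [((500, 1000),), ((1300, 1800),)]

    def test_short_utr_clips_window_at_utr_start(self):
        g = gene(utrs=[[(100, 400)]])
        (f,) = build_isoform_windows(g, window=500)
        assert f.intervals == ((100, 400),)
        assert f.length <= 500

    def test_spliced_window_crosses_junction(self):
        # 3'UTR split over two exons: last 500 nt of transcript sequence
        g = gene(utrs=[[(0, 300), (1000, 1300)]])
        (f,) = build_isoform_windows(g, window=500)
        assert f.intervals == ((100, 300), (1000, 1300))
        assert f.length == 500

    def test_bad_parameters_raise(self):
        g = gene(utrs=[[(0, 1000)]])
        with pytest.raises(ValueError):
            build_isoform_windows(g, merge_dist=0)
        with pytest.raises(ValueError):
            build_isoform_windows(g, coord_space="nonsense")

    def test_minus_strand_mirrors_plus(self):
        # mirror of ends 1000/1800 on '+' around position 2000
        gp = gene(strand="+", utrs=[[(0, 1000)], [(0, 1800)]])
        gm = gene(strand="-", utrs=[[(1000, 2000)], [(200, 2000)]])
        fp = build_isoform_windows(gp)
        fm = build_isoform_windows(gm)
        mirrored = [
            tuple(sorted((2000 - e, 2000 - s) for s, e in f.intervals))
            for f in fm
        ]
        assert [list(f.intervals) for f in fp] == [sorted(m) for m in mirrored]

    def test_windows_never_overlap_within_gene(self):
        genes = simulate_annotation(SimScenario(n_genes=60, merge_rate=0.4), seed=11)
        for g in genes:
            feats = build_isoform_windows(g)
            covered = set()
            for f in feats:
                for s, e in f.intervals:
                    span = set(range(s, e))
                    assert not covered & span
                    covered |= span

    def test_smaller_merge_dist_never_reduces_feature_count(self):
        genes = simulate_annotation(SimScenario(n_genes=60, merge_rate=0.4), seed=5)
        for g in genes:
            n500 = len(build_isoform_windows(g, merge_dist=500))
            n250 = len(build_isoform_windows(g, merge_dist=250))
            assert n250 >= n500


class TestClassifyPair:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([(100, 600)], [(100, 900)], TANDEM),  # overlapping
            ([(100, 600)], [(600, 900)], TANDEM),  # directly adjacent
            ([(100, 600)], [(2000, 2500)], ALE),  # gap > 0
        ],
    )
    def test_geometry(self, a, b, expected):
        assert classify_pair(a, b) == expected


class TestLoading:
    GTF = """\
chr1\ttest\tthree_prime_utr\t101\t600\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tthree_prime_utr\t101\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t2";
chr1\ttest\tthree_prime_utr\t901\t1300\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t2";
"""

    # same gene as BED12: t1 = single exon CDS[0,100) UTR[100,600);
    # t2 = two exons with UTR [100,400)+[900,1300)
    BED = (
        "chr1\t0\t600\tgA|gA.t1\t0\t+\t0\t100\t0\t1\t600,\t0,\n"
        "chr1\t0\t1300\tgA|gA.t2\t0\t+\t0\t100\t0\t2\t400,400,\t0,900,\n"
    )

    def test_gtf_and_bed12_give_identical_models(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(self.GTF)
        bed = tmp_path / "a.bed"
        bed.write_text(self.BED)
        (g1,) = load_gene_models(gtf)
        (g2,) = load_gene_models(bed)
        assert g1.gene_id == g2.gene_id == "gA"
        t1 = {t.transcript_id: t for t in g1.transcripts}
        t2 = {t.transcript_id: t for t in g2.transcripts}
        assert set(t1) == set(t2)
        for k in t1:
            assert t1[k].utr3_intervals == t2[k].utr3_intervals
            assert t1[k].end3 == t2[k].end3

    def test_noncoding_transcript_dropped(self, tmp_path):
        bed = tmp_path / "nc.bed"
        bed.write_text(
            "chr1\t0\t600\tgB|gB.t1\t0\t+\t0\t100\t0\t1\t600,\t0,\n"
            "chr1\t0\t500\tgB|gB.t2\t0\t+\t0\t0\t0\t1\t500,\t0,\n"
        )
        (g,) = load_gene_models(bed)
        assert [t.transcript_id for t in g.transcripts] == ["gB.t1"]

    def test_mixed_strand_gene_rejected(self, tmp_path):
        bed = tmp_path / "mix.bed"
        bed.write_text(
            "chr1\t0\t600\tgC|gC.t1\t0\t+\t0\t100\t0\t1\t600,\t0,\n"
            "chr1\t0\t600\tgC|gC.t2\t0\t-\t500\t600\t0\t1\t600,\t0,\n"
        )
        with pytest.raises(ValueError, match="mixed"):
            load_gene_models(bed)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t0\t600\tonly-four-columns\n")
        with pytest.raises(ValueError):
            load_gene_models(bad)


def test_bed12_writer_round_trips_gene_models(tmp_path):
    from dlocal.annotation import gene_models_to_bed12
    from dlocal.simulate import SimScenario, simulate_annotation

    genes = simulate_annotation(SimScenario(n_genes=20), seed=8)
    path = tmp_path / "ann.bed"
    gene_models_to_bed12(genes, path)
    reloaded = {g.gene_id: g for g in load_gene_models(path)}
    for g in genes:
        r = reloaded[g.gene_id]
        assert r.strand == g.strand and len(r.transcripts) == len(g.transcripts)
        for t_orig, t_new in zip(
            sorted(g.transcripts, key=lambda t: t.transcript_id),
            sorted(r.transcripts, key=lambda t: t.transcript_id),
        ):
            # the writer spends one base on a placeholder CDS at the 5' end
            assert t_new.end3 == t_orig.end3
            assert abs(
                sum(e - s for s, e in t_new.utr3_intervals)
                - sum(e - s for s, e in t_orig.utr3_intervals)
            ) <= 1


def test_merge_intervals_rejects_empty_interval():
    with pytest.raises(ValueError):
        merge_intervals([(5, 5)])
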