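"""Distal-fraction statistics, isoDend calling, and cohort comparisons."""

import numpy as np
import pandas as pd
import pytest

from dlocal.isoforms import (
    DISTAL,
    PROXIMAL,
    analyze_isoforms,
    df_variance_comparison,
    distal_fraction,
    length_comparison,
    preference_summary,
    select_top_two,
    test_isoform_localization,
)


def frame(rows, ids=None, samples=None):
    rows = np.asarray(rows)
    ids = ids or [f"iso{i+1}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=ids, columns=samples)


class TestSelectTopTwo:
    def test_two_isoforms_ordered_by_position(self):
        assert select_top_two(frame([[30, 5], [10, 40]])) == ("iso1", "iso2")

    def test_low_read_sample_skipped_in_fraction_sums(self):
        # A: fractions (0.8,0.1,0.1); B: (0.2,0.7,0.1); C skipped (<10 reads)
        counts = frame(
            [[80, 20, 4], [10, 70, 3], [10, 10, 2]], samples=["A", "B", "C"]
        )
        assert select_top_two(counts) == ("iso1", "iso2")

    def test_tie_broken_by_raw_reads_then_distality(self):
        # iso1 and iso2 tie on fraction sum and raw reads; distality decides
        counts = frame([[10, 40], [40, 10], [50, 50]])
        pair = select_top_two(counts)
        assert pair == ("iso2", "iso3")

    def test_no_qualifying_sample_returns_none(self):
        assert select_top_two(frame([[3, 2], [1, 2]])) is None

    def test_single_isoform_rejected(self):
        with pytest.raises(ValueError):
            select_top_two(frame([[50, 50]]))


class TestDistalFraction:
    @pytest.mark.parametrize(
        "d,p,expected", [(0, 12, 0.0), (30, 10, 0.75), (6, 6, 0.5)]
    )
    def test_values(self, d, p, expected):
        assert distal_fraction(d, p) == pytest.approx(expected)

    def test_below_min_reads_undefined(self):
        assert np.isnan(distal_fraction(4, 5))  # total 9 < 10

    def test_scale_invariance(self, rng):
        for _ in range(20):
            d, p = int(rng.integers(0, 50)), int(rng.integers(1, 50))
            if d + p < 10:
                continue
            k = int(rng.integers(2, 9))
            assert distal_fraction(d, p) == pytest.approx(
                distal_fraction(k * d, k * p)
            )


class TestIsoformCall:
    def test_five_concordant_cells_called_distal(self):
        p, n, iso, pref = test_isoform_localization([0.2, 0.3, 0.1, 0.25, 0.15])
        assert (n, iso, pref) == (5, True, DISTAL)
        assert p == pytest.approx(0.0625)

    def test_alternating_deltas_not_called(self):
        p, n, iso, pref = test_isoform_localization([0.2, -0.2, 0.2, -0.2, 0.2])
        assert p > 0.1 and not iso

    def test_four_pairs_untestable(self):
        p, n, iso, _ = test_isoform_localization([0.3, 0.3, 0.3, 0.3])
        assert n == 4 and not iso and np.isnan(p)

    def test_all_zero_deltas_degenerate(self):
        p, n, iso, _ = test_isoform_localization([0.0] * 8)
        assert p == 1.0 and not iso

    def test_negative_shift_prefers_proximal(self):
        p, _, iso, pref = test_isoform_localization([-0.2] * 8)
        assert iso and pref == PROXIMAL


def fake_records(n_iso_distal, n_iso_prox, n_rest_distal, n_rest_prox):
    rows = []
    k = 0
    for count, isodend, pref in [
        (n_iso_distal, True, DISTAL),
        (n_iso_prox, True, PROXIMAL),
        (n_rest_distal, False, DISTAL),
        (n_rest_prox, False, PROXIMAL),
    ]:
        for _ in range(count):
            rows.append((f"g{k}", "a", "b", "ALE", 8, 0.05, isodend, pref,
                         0.1, 0.1, 0.01, 0.01))
            k += 1
    return pd.DataFrame(
        rows,
        columns=["gene_id", "proximal", "distal", "cls", "n_pairs", "p",
                 "isodend", "preferred", "mean_delta", "median_delta",
                 "df_var_soma", "df_var_dendrite"],
    ).set_index("gene_id")


class TestPreferenceSummary:
    def test_reported_cohort_counts_give_expected_odds_ratio(self):
        # 298 isoDend (191 distal) vs 3340 remaining tested (1410 distal)
        rec = fake_records(191, 107, 1410, 1930)
        out = preference_summary(rec)
        assert out["table"].tolist() == [[191, 107], [1410, 1930]]
        assert out["odds_ratio"] == pytest.approx(2.44, abs=0.01)
        assert out["p"] < 1e-10

    def test_identical_rows_give_unit_odds_ratio(self):
        out = preference_summary(fake_records(30, 20, 30, 20))
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_zero_cell_convention(self):
        out = preference_summary(fake_records(10, 0, 5, 5))
        assert out["odds_ratio"] == np.inf


class TestLengthComparison:
    def test_equal_lengths_null(self):
        rec = fake_records(5, 0, 0, 0)
        lengths = {"a": 500, "b": 500}
        out = length_comparison(rec, lengths)
        assert out.loc["ALE", "t"] == 0.0
        assert out.loc["ALE", "p"] == 1.0

    def test_matches_hand_computed_t(self):
        diffs = np.array([100.0, 120.0, 80.0, 110.0, 90.0])
        rec = fake_records(5, 0, 0, 0)
        lengths_by_gene = {}
        rows = []
        for i, (g, r) in enumerate(rec.iterrows()):
            rows.append((g, f"p{i}", f"d{i}"))
            lengths_by_gene[f"d{i}"] = 500 + diffs[i]
            lengths_by_gene[f"p{i}"] = 500
        rec = rec.copy()
        rec["proximal"] = [r[1] for r in rows]
        rec["distal"] = [r[2] for r in rows]
        out = length_comparison(rec, lengths_by_gene)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert out.loc["ALE", "t"] == pytest.approx(expected_t)

    def test_single_pair_flagged_untestable(self):
        rec = fake_records(1, 0, 0, 0)
        out = length_comparison(rec, {"a": 900, "b": 500})
        assert out.loc["ALE", "n"] == 1
        assert np.isnan(out.loc["ALE", "t"])


class TestOnSyntheticStudy:
    def test_planted_isodend_recovery_and_null_control(self, small_bundle):
        res = analyze_isoforms(
            small_bundle.matrix, small_bundle.features,
            gene_models=small_bundle.gene_models,
        )
        truth = small_bundle.plan["cls"]
        tested = set(res.records.index[res.records["p"].notna()])
        called = set(res.records.index[res.records["isodend"]])
        planted = set(truth.index[truth == "isodend"]) & tested
        assert len(planted) >= 20
        sens = len(called & planted) / len(planted)
        assert sens >= 0.8
        null = tested - set(truth.index[truth == "isodend"])
        fpr = len(called & null) / len(null)
        assert fpr <= 0.1 + 2 * np.sqrt(0.1 * 0.9 / len(null))

    def test_proximal_distal_identities_match_truth(self, small_bundle):
        res = analyze_isoforms(
            small_bundle.matrix, small_bundle.features,
            gene_models=small_bundle.gene_models,
        )
        truth = small_bundle.truth
        rec = res.records[res.records["isodend"]]
        planted = rec.index.intersection(
            truth.index[truth["cls"] == "isodend"]
        )
        assert (
            rec.loc[planted, "proximal"] == truth.loc[planted, "proximal_id"]
        ).all()
        assert (
            rec.loc[planted, "distal"] == truth.loc[planted, "distal_id"]
        ).all()

    def test_df_variance_comparison_deterministic_and_inflating(self, small_bundle):
        res = analyze_isoforms(
            small_bundle.matrix, small_bundle.features,
            gene_models=small_bundle.gene_models,
        )
        a = df_variance_comparison(res, reps=50, seed=9)
        b = df_variance_comparison(res, reps=50, seed=9)
        assert a["downsampled_mean_fraction"] == b["downsampled_mean_fraction"]
        assert a["table"].tolist() == b["table"].tolist()
        # downsampling soma to 10 reads adds binomial noise: the fraction of
        # isoDend genes with soma-more-variable DF should not drop
        assert (
            a["downsampled_mean_fraction"]
            >= a["frac_isodend_soma_more_variable"] - 0.05
        )
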