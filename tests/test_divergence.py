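import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from panelscan import divergence as dvg
from panelscan._bins import BinSpec
from panelscan.io import chromosome_sort_key

from conftest import make_map, make_matrix


def two_group_counts(rows):
    """Build a counts frame from (countA_a, countA_b, countB_a, countB_b) rows."""
    df = pd.DataFrame(rows, columns=["countA_a", "countA_b", "countB_a", "countB_b"])
    df["snp_id"] = [f"s{i}" for i in range(len(df))]
    df["chromosome"] = "1"
    df["position_bp"] = np.arange(1, len(df) + 1) * 100
    df.attrs["group_a"] = "Temperate"
    df.attrs["group_b"] = "Tropical"
    return df


class TestGroupAlleleCounts:
    def test_heterozygote_contributes_one_copy_of_each_allele(self):
        gm = make_matrix([[0], [1], [2]])
        groups = pd.Series({"L0": "A", "L1": "A", "L2": "A", })
        gm2 = make_matrix([[0], [1], [2], [0]], ["L0", "L1", "L2", "L3"])
        groups = pd.Series({"L0": "A", "L1": "A", "L2": "A", "L3": "B"})
        counts = dvg.group_allele_counts(gm2, make_map(1), groups, "A", "B")
        assert counts.countA_a[0] == 3 and counts.countA_b[0] == 3
        assert counts.freqA_b[0] == pytest.approx(0.5)

    def test_all_missing_group_excluded_with_tally(self):
        gm = make_matrix([[0], [-1]], ["L0", "L1"])
        groups = pd.Series({"L0": "A", "L1": "B"})
        counts = dvg.group_allele_counts(gm, make_map(1), groups, "A", "B")
        assert np.isnan(counts.freqB_b[0])
        assert counts.attrs["n_excluded_empty_group"] == 1

    def test_counts_conserve_allele_copies(self, rng):
        gm = make_matrix(rng.integers(-1, 3, size=(20, 50)))
        groups = pd.Series({lid: ("A" if i < 12 else "B")
                            for i, lid in enumerate(gm.line_ids)})
        counts = dvg.group_allele_counts(gm, make_map(50), groups, "A", "B")
        called_a = (gm.calls[:12] >= 0).sum(axis=0)
        assert ((counts.countA_a + counts.countA_b) == 2 * called_a).all()


class TestUniqueSnps:
    def test_private_allele_credited_to_polymorphic_group(self):
        counts = two_group_counts([(10, 5, 12, 0)])
        unique, _ = dvg.screen_unique_snps(counts)
        assert unique[0] == "Temperate"

    def test_monomorphic_in_both_or_polymorphic_in_both_is_none(self):
        counts = two_group_counts([(10, 0, 12, 0), (10, 5, 12, 3)])
        unique, _ = dvg.screen_unique_snps(counts)
        assert unique.tolist() == ["none", "none"]

    def test_inverse_reading_credits_monomorphic_group(self):
        counts = two_group_counts([(10, 5, 12, 0)])
        unique, _ = dvg.screen_unique_snps(counts, credit="monomorphic")
        assert unique[0] == "Tropical"

    def test_per_chromosome_table_sums_to_total(self):
        counts = two_group_counts([(10, 5, 12, 0), (0, 9, 4, 4), (3, 3, 2, 2)])
        _, table = dvg.screen_unique_snps(counts)
        total = table[table.chromosome == "Total"].iloc[0]
        per_chrom = table[table.chromosome != "Total"]
        assert total.unique_in_Temperate == per_chrom.unique_in_Temperate.sum() == 1
        assert total.unique_in_Tropical == per_chrom.unique_in_Tropical.sum() == 1


class TestChi2:
    def test_strong_divergence_hand_value(self):
        out = dvg.chi2_divergence((90, 10), (10, 90))
        assert out.chi2[0] == pytest.approx(128.0)
        assert out.p_value[0] < 0.001 and bool(out.significant[0])

    def test_identical_counts_not_significant(self):
        out = dvg.chi2_divergence((40, 60), (40, 60))
        assert out.chi2[0] == pytest.approx(0.0)
        assert not out.significant[0]

    def test_zero_marginal_is_untestable(self):
        out = dvg.chi2_divergence((10, 0), (12, 0))
        assert not out.testable[0]
        assert np.isnan(out.chi2[0])

    def test_matches_brute_force_and_scipy_on_random_tables(self, rng):
        tables = rng.integers(1, 200, size=(1000, 4))
        out = dvg.chi2_divergence(tables[:, :2], tables[:, 2:])
        for t, chi2 in zip(tables, out.chi2):
            o = np.array([[t[0], t[1]], [t[2], t[3]]], dtype=float)
            e = np.outer(o.sum(1), o.sum(0)) / o.sum()
            brute = ((o - e) ** 2 / e).sum()
            assert chi2 == pytest.approx(brute, rel=1e-10)
        # independent implementation: scipy without continuity correction
        sub = tables[:50]
        ref = [chi2_contingency([[t[0], t[1]], [t[2], t[3]]], correction=False)[0]
               for t in sub]
        np.testing.assert_allclose(out.chi2[:50], ref, rtol=1e-10)

    def test_symmetric_under_group_and_allele_swaps(self, rng):
        t = rng.integers(1, 100, size=(200, 4))
        base = dvg.chi2_divergence(t[:, :2], t[:, 2:]).chi2
        swap_groups = dvg.chi2_divergence(t[:, 2:], t[:, :2]).chi2
        swap_alleles = dvg.chi2_divergence(t[:, [1, 0]], t[:, [3, 2]]).chi2
        np.testing.assert_allclose(base, swap_groups, rtol=1e-12)
        np.testing.assert_allclose(base, swap_alleles, rtol=1e-12)


class TestVariationRanking:
    @pytest.mark.parametrize("fa, fb, expected", [
        (0.888, 0.118, 0.770),
        (0.855, 0.094, 0.761),
        (0.5, 0.5, 0.0),
    ])
    def test_absolute_difference(self, fa, fb, expected):
        assert dvg.allele_frequency_variation(fa, fb) == pytest.approx(expected)

    def test_designated_allele_does_not_matter(self, rng):
        p, q = rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)
        np.testing.assert_allclose(dvg.allele_frequency_variation(p, q),
                                   dvg.allele_frequency_variation(1 - p, 1 - q))

    def records(self, rows):
        df = pd.DataFrame(rows, columns=["chromosome", "position_bp", "freq_variation"])
        df["snp_id"] = [f"s{i}" for i in range(len(df))]
        df["freqA_b"] = 0.0
        df["freqB_b"] = df["freq_variation"]
        return df

    def test_descending_order_and_k_cap(self):
        rec = self.records([("1", 100, 0.3), ("1", 200, 0.9), ("1", 300, 0.5)])
        top = dvg.top_variant_snps(rec, k=2)
        assert top.freq_variation.tolist() == [0.9, 0.5]
        assert len(dvg.top_variant_snps(rec, k=10)) == 3

    def test_ties_break_by_chromosome_then_position(self):
        rec = self.records([("2", 100, 0.5), ("1", 500, 0.5)])
        top = dvg.top_variant_snps(rec, k=2)
        assert top.chromosome.tolist() == ["1", "2"]

    def test_ranking_matches_full_sort_oracle(self, rng):
        n = 10_000
        rec = self.records(list(zip(
            rng.choice(["1", "2", "10"], n),
            rng.integers(1, 10 ** 6, n),
            rng.uniform(0, 1, n).round(3),
        )))
        top = dvg.top_variant_snps(rec, k=50)
        oracle = sorted(
            rec.itertuples(),
            key=lambda r: (-r.freq_variation, chromosome_sort_key(r.chromosome),
                           r.position_bp))[:50]
        assert top.snp_id.tolist() == [r.snp_id for r in oracle]


class TestBinnedRatio:
    def make_records(self, smap, significant, testable=None):
        n = len(smap)
        return pd.DataFrame({
            "snp_id": smap.snp_id,
            "significant": significant,
            "testable": np.ones(n, dtype=bool) if testable is None else testable,
        })

    def test_ratio_is_significant_over_tested(self):
        smap = make_map(203, step=100)
        sig = np.zeros(203, dtype=bool)
        sig[:132] = True
        out = dvg.binned_variant_ratio(smap, self.make_records(smap, sig),
                                       BinSpec(min_snps_per_bin=1))
        assert out.iloc[0].variant_ratio == pytest.approx(132 / 203)
        assert out.iloc[0].variant_ratio == pytest.approx(0.6502, abs=5e-5)

    def test_zero_significant_gives_zero_ratio(self):
        smap = make_map(40, step=100)
        out = dvg.binned_variant_ratio(smap, self.make_records(smap, np.zeros(40, bool)),
                                       BinSpec(min_snps_per_bin=1))
        assert out.iloc[0].variant_ratio == 0.0

    def test_variant_and_nonvariant_ratios_are_complementary(self, rng):
        smap = make_map(500, step=50_000)
        sig = rng.random(500) < 0.3
        testable = rng.random(500) < 0.9
        out = dvg.binned_variant_ratio(smap, self.make_records(smap, sig, testable),
                                       BinSpec(min_snps_per_bin=1))
        ok = out.dropna(subset=["variant_ratio"])
        np.testing.assert_allclose(ok.variant_ratio + ok.non_variant_ratio, 1.0)
        # untestable SNPs excluded from the denominator
        assert out.n_tested.sum() == testable.sum()

    def test_null_type_i_error_within_three_se(self, rng):
        # property check at moderate scale; the acceptance suite runs 100k
        n = 20_000
        p = rng.uniform(0.05, 0.95, n)
        ca = rng.binomial(300, p)
        cb = rng.binomial(260, p)
        out = dvg.chi2_divergence(np.column_stack([300 - ca, ca]),
                                  np.column_stack([260 - cb, cb]), alpha=0.001)
        rate = out.significant.mean()
        se = np.sqrt(0.001 * 0.999 / n)
        assert abs(rate - 0.001) < 3 * se

    def test_planted_window_attains_top_ratio(self, emulated_panel):
        b = emulated_panel
        rec = dvg.divergence_scan(b.genotypes, b.snp_map, b.groups,
                                  "Temperate", "Tropical")
        out = dvg.binned_variant_ratio(b.snp_map, rec, BinSpec(min_snps_per_bin=5))
        ok = out.dropna(subset=["variant_ratio"])
        w = ok[(ok.chromosome == "2") & (ok.bin_start_bp == 130_000_000)]
        assert len(w) == 1
        assert w.variant_ratio.iloc[0] == pytest.approx(ok.variant_ratio.max())
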