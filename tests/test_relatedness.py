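import numpy as np
import pandas as pd
import pytest

from panelscan import relatedness as rel
from panelscan._bins import BinSpec
from panelscan.errors import DomainError

from conftest import make_map, make_matrix


class TestSimilarityRatio:
    def test_identical_lines_score_one(self):
        res = rel.similarity_ratio([0, 1, 2, 0], [0, 1, 2, 0])
        assert res.similarity_ratio == 1.0

    def test_whole_genotype_identity_hand_count(self):
        # AA,AG,GG,AA vs AA,AG,AA,AA -> 3 of 4 match (het matches het)
        res = rel.similarity_ratio([0, 1, 2, 0], [0, 1, 0, 0])
        assert res.n_matching == 3 and res.n_compared == 4
        assert res.similarity_ratio == 0.75

    def test_missing_excluded_from_denominator(self):
        res = rel.similarity_ratio([0, -1], [0, 2])
        assert res.similarity_ratio == 1.0 and res.n_compared == 1

    def test_literal_total_denominator_counts_missing(self):
        res = rel.similarity_ratio([0, -1], [0, 2], denominator="total")
        assert res.n_compared == 2 and res.similarity_ratio == 0.5

    def test_no_shared_calls_is_nan(self):
        res = rel.similarity_ratio([-1], [0])
        assert np.isnan(res.similarity_ratio)


class TestSimilarityMatrix:
    def test_identical_panel_is_all_ones(self):
        gm = make_matrix([[0, 2, 1]] * 3)
        sim, report = rel.similarity_matrix(gm)
        assert (sim.to_numpy() == 1.0).all()
        assert report["mean"] == 1.0

    def test_matches_brute_force_double_loop(self, rng):
        calls = rng.integers(-1, 3, size=(10, 80)).astype(np.int8)
        gm = make_matrix(calls)
        sim, _ = rel.similarity_matrix(gm)
        for i in range(10):
            for j in range(10):
                both = (calls[i] >= 0) & (calls[j] >= 0)
                expect = (calls[i][both] == calls[j][both]).sum() / both.sum()
                assert sim.iloc[i, j] == pytest.approx(expect)

    def test_symmetry_and_unit_diagonal(self, rng):
        calls = rng.integers(-1, 3, size=(8, 60)).astype(np.int8)
        sim, _ = rel.similarity_matrix(make_matrix(calls))
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)
        np.testing.assert_allclose(np.diag(sim.to_numpy()), 1.0)

    def test_line_permutation_permutes_but_preserves_values(self, rng):
        calls = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        gm = make_matrix(calls)
        perm = rng.permutation(6)
        gm2 = make_matrix(calls[perm], [gm.line_ids[i] for i in perm])
        sim1, _ = rel.similarity_matrix(gm)
        sim2, _ = rel.similarity_matrix(gm2)
        pd.testing.assert_frame_equal(sim1, sim2.loc[sim1.index, sim1.columns])


class TestMostSimilar:
    def sim_frame(self, vals):
        ids = list(vals)
        df = pd.DataFrame(1.0, index=ids, columns=ids)
        for lid, v in vals.items():
            df.loc["focal", lid] = df.loc[lid, "focal"] = v
        return df

    def test_top_k_descending(self):
        sim = self.sim_frame({"focal": 1.0, "a": 0.9, "b": 0.8, "c": 0.7})
        top = rel.most_similar_lines(sim, "focal", k=2)
        assert top.line_id.tolist() == ["a", "b"]

    def test_ties_break_lexicographically(self):
        sim = self.sim_frame({"focal": 1.0, "b": 0.8, "a": 0.8, "c": 0.1})
        top = rel.most_similar_lines(sim, "focal", k=2)
        assert top.line_id.tolist() == ["a", "b"]

    def test_k_beyond_panel_returns_all_others(self):
        sim = self.sim_frame({"focal": 1.0, "a": 0.9, "b": 0.5})
        assert len(rel.most_similar_lines(sim, "focal", k=99)) == 2

    def test_matches_sort_oracle_on_simulated_panel(self, rng):
        ids = [f"L{i:03d}" for i in range(200)]
        vals = dict(zip(ids, rng.uniform(0, 1, 200).round(3)))
        vals["focal"] = 1.0
        sim = self.sim_frame(vals)
        top = rel.most_similar_lines(sim, "focal", k=30)
        oracle = sorted((lid for lid in vals if lid != "focal"),
                        key=lambda l: (-vals[l], l))[:30]
        assert top.line_id.tolist() == oracle


class TestBinnedSimilarity:
    def test_focal_only_subset_is_all_ones(self):
        gm = make_matrix([[0, 1, 2, 0]], ["F"])
        out = rel.binned_similarity(gm, make_map(4), "F", ["F"],
                                    BinSpec(min_snps_per_bin=1))
        assert (out.per_line.similarity.dropna() == 1.0).all()

    def test_single_bin_equals_whole_genome_ratio(self, rng):
        calls = rng.integers(0, 3, size=(3, 50)).astype(np.int8)
        gm = make_matrix(calls, ["F", "A", "B"])
        smap = make_map(50, step=100)
        out = rel.binned_similarity(gm, smap, "F", ["A", "B"],
                                    BinSpec(min_snps_per_bin=1))
        whole = rel.similarity_ratio(calls[0], calls[1]).similarity_ratio
        got = out.per_line[(out.per_line.line_id == "A")].similarity.iloc[0]
        assert got == pytest.approx(whole)

    def test_per_bin_values_match_brute_force(self, rng):
        n = 200
        calls = rng.integers(-1, 3, size=(4, n)).astype(np.int8)
        gm = make_matrix(calls, ["F", "A", "B", "C"])
        smap = make_map(n, step=100_000)  # spans 2 bins of 10 Mb
        out = rel.binned_similarity(gm, smap, "F", ["A", "B", "C"],
                                    BinSpec(min_snps_per_bin=1))
        for row in out.per_line.itertuples():
            sel = ((smap.position_bp - 1 >= row.bin_start_bp)
                   & (smap.position_bp - 1 < row.bin_end_bp))
            li = gm.line_index(row.line_id)
            expect = rel.similarity_ratio(calls[0][sel], calls[li][sel])
            assert row.similarity == pytest.approx(expect.similarity_ratio, nan_ok=True)


class TestConservedRegions:
    def per_bin(self, means, chrom="1"):
        n = len(means)
        return pd.DataFrame({
            "chromosome": chrom, "bin_index": range(n),
            "bin_start_bp": np.arange(n) * 10_000_000,
            "bin_end_bp": (np.arange(n) + 1) * 10_000_000,
            "n_snps": 40, "mean_similarity": means, "flag": "none",
        })

    def test_runs_split_at_low_bins(self):
        regions = rel.conserved_regions(self.per_bin([0.9, 0.88, 0.7, 0.86]))
        assert len(regions) == 2
        assert regions.iloc[0].start_bin == 0 and regions.iloc[0].end_bin == 1
        assert regions.iloc[1].start_bin == 3 and regions.iloc[1].end_bin == 3

    def test_threshold_is_strict(self):
        regions = rel.conserved_regions(self.per_bin([0.85, 0.84]))
        assert regions.empty

    def test_dropped_bins_break_runs(self):
        pb = self.per_bin([0.9, 0.9, 0.9])
        pb.loc[1, "flag"] = "dropped"
        pb.loc[1, "mean_similarity"] = np.nan
        regions = rel.conserved_regions(pb)
        assert len(regions) == 2

    def test_planted_founder_segment_recovered_within_one_bin(self, emulated_panel):
        b = emulated_panel
        seg = b.manifest.segments[0]
        sim, _ = rel.similarity_matrix(b.genotypes)
        top = rel.most_similar_lines(sim, seg["founder"], k=30)
        out = rel.binned_similarity(b.genotypes, b.snp_map, seg["founder"],
                                    top.line_id.tolist(), BinSpec(min_snps_per_bin=5))
        regions = rel.conserved_regions(out.per_bin, threshold=0.85)
        on7 = regions[regions.chromosome == seg["chromosome"]]
        big = on7.loc[on7.n_bins.idxmax()]
        assert abs(big.bin_start_bp - seg["start_bp"]) <= 10_000_000
        assert abs(big.bin_end_bp - seg["end_bp"]) <= 10_000_000


class TestKinship:
    def test_single_snp_hand_value(self):
        gm = make_matrix([[2], [0]])
        k = rel.vanraden_kinship(gm)
        np.testing.assert_allclose(k.to_numpy(), [[2, -2], [-2, 2]])

    def test_duplicated_line_attains_max_off_diagonal(self, rng):
        calls = rng.integers(0, 3, size=(10, 100)).astype(np.int8)
        calls[9] = calls[0]
        k = rel.vanraden_kinship(make_matrix(calls)).to_numpy()
        off = k[np.triu_indices(10, 1)]
        assert k[0, 9] == pytest.approx(off.max())
        assert k[0, 0] == pytest.approx(k[9, 9])

    def test_matches_brute_force_double_loop(self, rng):
        calls = rng.integers(-1, 3, size=(20, 50)).astype(np.int8)
        gm = make_matrix(calls)
        k = rel.vanraden_kinship(gm).to_numpy()
        d = calls.astype(float)
        d[calls < 0] = np.nan
        p = np.nanmean(d, axis=0) / 2
        poly = (p > 0) & (p < 1)
        denom = 2 * np.sum(p[poly] * (1 - p[poly]))
        for i in range(20):
            for j in range(20):
                z = 0.0
                for s in np.flatnonzero(poly):
                    zi = d[i, s] - 2 * p[s] if np.isfinite(d[i, s]) else 0.0
                    zj = d[j, s] - 2 * p[s] if np.isfinite(d[j, s]) else 0.0
                    z += zi * zj
                assert k[i, j] == pytest.approx(z / denom, rel=1e-9)

    def test_snp_order_invariance_and_symmetry(self, rng):
        calls = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        gm = make_matrix(calls)
        k1 = rel.vanraden_kinship(gm).to_numpy()
        perm = rng.permutation(40)
        k2 = rel.vanraden_kinship(make_matrix(calls[:, perm])).to_numpy()
        np.testing.assert_allclose(k1, k2, atol=1e-12)
        np.testing.assert_allclose(k1, k1.T, atol=1e-12)

    def test_all_monomorphic_is_domain_error(self):
        with pytest.raises(DomainError):
            rel.vanraden_kinship(make_matrix([[0, 0], [0, 0]]))


class TestKinshipDistribution:
    def test_all_negative_with_clipping_gives_unit_zero_mass(self):
        k = pd.DataFrame([[1.0, -0.2], [-0.2, 1.0]])
        d = rel.kinship_distribution(k)
        assert d["fraction_zero"] == 1.0

    def test_clipping_off_changes_nothing(self):
        k = pd.DataFrame([[1.0, -0.2], [-0.2, 1.0]])
        d = rel.kinship_distribution(k, clip_negative=False)
        assert d["fraction_zero"] == 0.0

    def test_histogram_counts_sum_to_pair_count(self, rng):
        n = 15
        m = rng.normal(0, 0.3, (n, n))
        k = pd.DataFrame((m + m.T) / 2)
        d = rel.kinship_distribution(k)
        assert d["histogram"]["count"].sum() == n * (n - 1) // 2
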