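"""Between-group allele-frequency divergence.

Compares two groups of inbred lines SNP by SNP: unique (private-allele)
SNP screening, a Pearson chi-square test on the 2x2 allele-count table at
a fixed per-SNP significance level (0.001 by default, no multiple-testing
correction), ranking by absolute allele-frequency difference, and the
per-bin ratio of significantly variant SNPs to tested SNPs.

The chi-square test is computed on allele counts (two per called line,
one per allele for a heterozygote), without continuity correction, df = 1.
A SNP whose 2x2 table has a zero marginal (an allele absent from both
groups, or a group with no calls) is untestable and excluded from both
the numerator and denominator of the binned ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._bins import BinSpec, bin_assignments, bin_grid
from .errors import ContractError
from .io import GenotypeMatrix, SnpMap, chromosome_sort_key

logger = logging.getLogger(__name__)


def group_allele_counts(matrix: GenotypeMatrix, smap: SnpMap,
                        groups: pd.Series, group_a: str, group_b: str) -> pd.DataFrame:
    """Allele copy counts and allele_b frequency per SNP for two groups.

    Columns ``countA_a``/``countA_b`` are copies of allele_a/allele_b among
    non-missing calls in ``group_a`` (likewise B); frequencies are NaN for
    a group with zero called alleles at the SNP (such SNPs are logged and
    later marked untestable).
    """
    groups = pd.Series(groups)
    out = {"snp_id": smap.snp_id, "chromosome": smap.chromosome,
           "position_bp": smap.position_bp}
    for tag, label in (("A", group_a), ("B", group_b)):
        members = groups.index[groups == label]
        if len(members) == 0:
            raise ContractError(f"group {label!r} is empty")
        idx = np.array([matrix.line_index(m) for m in members])
        d = matrix.calls[idx]
        called = d >= 0
        count_b = np.where(called, d, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_b = np.where(total > 0, count_b / total, np.nan)
        out[f"count{tag}_a"] = total - count_b
        out[f"count{tag}_b"] = count_b
        out[f"freq{tag}_b"] = freq_b
    df = pd.DataFrame(out)
    df.attrs["group_a"] = group_a
    df.attrs["group_b"] = group_b
    n_empty = int((df[["freqA_b", "freqB_b"]].isna().any(axis=1)).sum())
    if n_empty:
        logger.info("%d SNP(s) with zero called alleles in a group; excluded from tests",
                    n_empty)
    df.attrs["n_excluded_empty_group"] = n_empty
    return df


def screen_unique_snps(counts: pd.DataFrame, credit: str = "polymorphic"
                       ) -> tuple[pd.Series, pd.DataFrame]:
    """Flag private-allele SNPs and tally them per chromosome.

    A SNP is *unique* when one group is polymorphic (both alleles present)
    and the other is monomorphic (exactly one allele present).  With
    ``credit="polymorphic"`` (default) the SNP is credited to the
    polymorphic group; ``credit="monomorphic"`` applies the inverse
    reading.  Returns (per-SNP unique_to labels, per-chromosome table).
    """
    if credit not in ("polymorphic", "monomorphic"):
        raise ContractError("credit must be 'polymorphic' or 'monomorphic'")
    ga, gb = counts.attrs.get("group_a", "A"), counts.attrs.get("group_b", "B")
    polyA = (counts["countA_a"] > 0) & (counts["countA_b"] > 0)
    polyB = (counts["countB_a"] > 0) & (counts["countB_b"] > 0)
    monoA = ((counts["countA_a"] > 0) ^ (counts["countA_b"] > 0))
    monoB = ((counts["countB_a"] > 0) ^ (counts["countB_b"] > 0))
    unique = np.full(len(counts), "none", dtype=object)
    a_flag, b_flag = (ga, gb) if credit == "polymorphic" else (gb, ga)
    unique[(polyA & monoB).to_numpy()] = a_flag
    unique[(polyB & monoA).to_numpy()] = b_flag
    unique_to = pd.Series(unique, index=counts.index, name="unique_to")

    chroms = sorted(set(counts["chromosome"]), key=chromosome_sort_key)
    rows = []
    for chrom in chroms:
        sel = counts["chromosome"] == chrom
        rows.append({
            "chromosome": chrom,
            f"unique_in_{ga}": int(((unique_to == ga) & sel).sum()),
            f"unique_in_{gb}": int(((unique_to == gb) & sel).sum()),
        })
    table = pd.DataFrame(rows)
    total = {"chromosome": "Total",
             f"unique_in_{ga}": int((unique_to == ga).sum()),
             f"unique_in_{gb}": int((unique_to == gb).sum())}
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    return unique_to, table


def chi2_divergence(counts_a, counts_b, alpha: float = 0.001) -> pd.DataFrame:
    """Pearson chi-square (df=1, no continuity correction) on 2x2 allele counts.

    ``counts_a``/``counts_b`` are (allele_a copies, allele_b copies) per
    group, scalars or aligned arrays.  Untestable SNPs (zero marginal) get
    NaN statistics; cells with expected count < 5 raise a low-count
    advisory flag but are still computed.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    # rows: groups; columns: alleles
    o11, o12 = a[..., 0], a[..., 1]
    o21, o22 = b[..., 0], b[..., 1]
    r1, r2 = o11 + o12, o21 + o22
    c1, c2 = o11 + o21, o12 + o22
    n = r1 + r2
    testable = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(testable, n * (o11 * o22 - o12 * o21) ** 2
                        / (r1 * r2 * c1 * c2), np.nan)
        expected_min = np.min(
            np.stack([r1 * c1, r1 * c2, r2 * c1, r2 * c2]), axis=0) / np.where(n > 0, n, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    out = pd.DataFrame({
        "chi2": np.ravel(chi2),
        "p_value": np.ravel(p),
        "significant": np.ravel(np.where(testable, p < alpha, False)).astype(bool),
        "testable": np.ravel(testable),
        "low_expected": np.ravel(np.where(testable, expected_min < 5, False)).astype(bool),
    })
    return out


def allele_frequency_variation(freq_a, freq_b) -> np.ndarray | float:
    """Absolute allele-frequency difference for the same designated allele."""
    v = np.abs(np.asarray(freq_a, dtype=float) - np.asarray(freq_b, dtype=float))
    return float(v) if v.ndim == 0 else v


def divergence_scan(matrix: GenotypeMatrix, smap: SnpMap, groups: pd.Series,
                    group_a: str, group_b: str, alpha: float = 0.001,
                    credit: str = "polymorphic") -> pd.DataFrame:
    """Full per-SNP divergence record table between two groups.

    Lines outside the two named groups (e.g. "Mixed") are ignored.
    """
    counts = group_allele_counts(matrix, smap, groups, group_a, group_b)
    test = chi2_divergence(counts[["countA_a", "countA_b"]].to_numpy(),
                           counts[["countB_a", "countB_b"]].to_numpy(), alpha=alpha)
    unique_to, _ = screen_unique_snps(counts, credit=credit)
    rec = counts.copy()
    for col in test.columns:
        rec[col] = test[col].to_numpy()
    rec["freq_variation"] = allele_frequency_variation(rec["freqA_b"], rec["freqB_b"])
    rec["unique_to"] = unique_to.to_numpy()
    rec.attrs.update(counts.attrs)
    rec.attrs["alpha"] = alpha
    return rec


def top_variant_snps(records: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k SNPs by allele-frequency variation.

    Descending by freq_variation; ties broken by (chromosome, position)
    ascending.  Only testable SNPs with defined variation are ranked; if k
    exceeds the record count, all are returned.
    """
    rec = records.loc[records["freq_variation"].notna()].copy()
    keys = [chromosome_sort_key(c) for c in rec["chromosome"]]
    rec["_k0"] = [t[0] for t in keys]
    rec["_k1"] = [t[1] for t in keys]
    rec["_k2"] = [t[2] for t in keys]
    rec = rec.sort_values(
        ["freq_variation", "_k0", "_k1", "_k2", "position_bp"],
        ascending=[False, True, True, True, True], kind="stable",
    ).drop(columns=["_k0", "_k1", "_k2"])
    cols = ["snp_id", "chromosome", "position_bp", "freqA_b", "freqB_b", "freq_variation"]
    return rec.head(min(k, len(rec)))[cols].reset_index(drop=True)


def binned_variant_ratio(smap: SnpMap, records: pd.DataFrame,
                         bin_spec: BinSpec | None = None) -> pd.DataFrame:
    """Per-bin counts of significant and tested SNPs and their ratio.

    Untestable SNPs are excluded from both numerator and denominator.
    Also emits the complementary non-variant ratio.  Bins whose tested
    count falls below the BinSpec minimum are flagged dropped.
    """
    bin_spec = bin_spec or BinSpec()
    if len(records) != len(smap):
        raise ContractError("records are not aligned to the map")
    asg = bin_assignments(smap, bin_spec)
    sig = records["significant"].to_numpy()[asg["snp_index"]]
    testable = records["testable"].to_numpy()[asg["snp_index"]]
    asg = asg.assign(sig=sig & testable, tested=testable)
    agg = asg.groupby(["chromosome", "bin_index"])[["sig", "tested"]].sum()
    grid = bin_grid(smap, bin_spec).set_index(["chromosome", "bin_index"])
    grid["n_significant"] = agg["sig"].reindex(grid.index).fillna(0).astype(int)
    grid["n_tested"] = agg["tested"].reindex(grid.index).fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(grid["n_tested"] > 0, grid["n_significant"] / grid["n_tested"], np.nan)
    grid["variant_ratio"] = ratio
    grid["non_variant_ratio"] = 1.0 - grid["variant_ratio"]
    dropped = grid["n_tested"] < bin_spec.min_snps_per_bin
    grid.loc[dropped, ["variant_ratio", "non_variant_ratio"]] = np.nan
    grid["flag"] = np.where(dropped, "dropped", "none")
    return grid.reset_index()[
        ["chromosome", "bin_index", "bin_start_bp", "bin_end_bp",
         "n_significant", "n_tested", "variant_ratio", "non_variant_ratio", "flag"]
    ]
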