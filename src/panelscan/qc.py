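"""Per-locus quality summaries and the two SNP filtering tiers.

The primary filter drops SNPs with missing rate > 0.20, heterozygosity
> 0.20 or minor allele frequency < 0.05 (boundary values are retained:
the inequalities are strict, as printed).  The stricter structure-analysis
subset keeps SNPs with missing rate < 0.05 and gene diversity > 0.45
(strict on both sides).

Allele frequencies come from allele counts: a heterozygote contributes one
copy of each allele, a missing call contributes nothing.  SNPs with zero
non-missing calls get NaN frequencies rather than a division by zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import gene_diversity_biallelic, pic_biallelic
from .errors import ContractError
from .io import GenotypeMatrix, SnpMap


def locus_summaries(matrix: GenotypeMatrix, smap: SnpMap) -> pd.DataFrame:
    """One row per SNP: n_called, missing_rate, het_rate, freq_b, maf, GD, PIC."""
    if matrix.n_snps != len(smap):
        raise ContractError("matrix and map have different SNP counts")
    if matrix.n_lines == 0:
        raise ContractError("matrix has no lines")
    d = matrix.calls
    called = d >= 0
    n_called = called.sum(axis=0)
    n_lines = matrix.n_lines
    missing_rate = 1.0 - n_called / n_lines
    n_het = (d == 1).sum(axis=0)
    count_b = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_called > 0, n_het / n_called, np.nan)
        freq_b = np.where(n_called > 0, count_b / (2 * n_called), np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    return pd.DataFrame({
        "snp_id": smap.snp_id,
        "n_called": n_called,
        "missing_rate": missing_rate,
        "het_rate": het_rate,
        "freq_b": freq_b,
        "maf": maf,
        "gene_diversity": gene_diversity_biallelic(freq_b),
        "pic": pic_biallelic(freq_b),
    })


def filter_primary(summaries: pd.DataFrame, max_missing: float = 0.20,
                   max_het: float = 0.20, min_maf: float = 0.05) -> np.ndarray:
    """Indices of SNPs surviving the primary filter (order preserved).

    Excludes strictly missing_rate > max_missing, het_rate > max_het and
    maf < min_maf; SNPs with undefined frequencies are excluded.
    """
    keep = (
        (summaries["missing_rate"].to_numpy() <= max_missing)
        & (summaries["het_rate"].to_numpy() <= max_het)
        & (summaries["maf"].to_numpy() >= min_maf)  # NaN compares False
    )
    return np.flatnonzero(keep)


def filter_structure_subset(summaries: pd.DataFrame, max_missing: float = 0.05,
                            min_gd: float = 0.45) -> np.ndarray:
    """Indices of SNPs in the stringent structure-analysis subset.

    Keeps strictly missing_rate < max_missing and gene_diversity > min_gd,
    with GD the uncorrected whole-panel estimator.
    """
    keep = (
        (summaries["missing_rate"].to_numpy() < max_missing)
        & (summaries["gene_diversity"].to_numpy() > min_gd)
    )
    return np.flatnonzero(keep)
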