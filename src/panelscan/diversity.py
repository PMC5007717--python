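"""Gene diversity (expected heterozygosity) and PIC, group summaries,
10-Mb binned genome scans and diversity-hotspot calling.

Gene diversity at a locus is the probability that two alleles drawn at
random from the population differ:

    GD = 1 - sum_u p_u^2                       (uncorrected)
    GD = (1 - sum_u p_u^2) / (1 - (1 + f) / n) (small-sample corrected,
                                                f = inbreeding coefficient)

The polymorphism information content is

    PIC = 1 - sum_u p_u^2 - sum_{u<v} 2 p_u^2 p_v^2

For a biallelic SNP both statistics are maximal at p = 0.5: GD = 0.500 and
PIC = 0.375.  The uncorrected estimator is the default: the correction
factor would push the biallelic maximum above 0.5, which the group
summaries here treat as the attainable ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._bins import BinSpec, aggregate_by_bin, check_same_grid
from .errors import ContractError, DomainError
from .io import GenotypeMatrix, SnpMap

__all__ = [
    "DiversityParams", "BinSpec", "gene_diversity", "pic",
    "gene_diversity_biallelic", "pic_biallelic",
    "group_diversity_table", "binned_scan", "call_hotspots",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class DiversityParams:
    """Estimator settings: inbreeding coefficient f and whether to apply
    the finite-sample correction 1 - (1+f)/n."""

    inbreeding_f: float = 0.0
    apply_correction: bool = False


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > _FREQ_TOL:
        raise ContractError(f"allele frequencies sum to {freqs.sum()!r}, not 1")
    return freqs


def gene_diversity(allele_freqs, n: int | None = None,
                   params: DiversityParams | None = None) -> float:
    """Gene diversity of one locus from its allele-frequency vector."""
    params = params or DiversityParams()
    freqs = _check_freqs(allele_freqs)
    d = 1.0 - float(np.sum(freqs ** 2))
    if params.apply_correction:
        if n is None:
            raise ContractError("sample size n is required for the corrected estimator")
        denom = 1.0 - (1.0 + params.inbreeding_f) / n
        if denom <= 0:
            raise DomainError(f"correction denominator 1-(1+f)/n = {denom} <= 0")
        d /= denom
    return d


def pic(allele_freqs) -> float:
    """Polymorphism information content of one locus."""
    freqs = _check_freqs(allele_freqs)
    s2 = np.sum(freqs ** 2)
    # sum_{u<v} 2 p_u^2 p_v^2 == (sum p^2)^2 - sum p^4
    cross = float(s2 ** 2 - np.sum(freqs ** 4))
    return 1.0 - float(s2) - cross


def gene_diversity_biallelic(freq_b) -> np.ndarray:
    """Vectorized uncorrected GD for biallelic loci: 2 p (1 - p)."""
    p = np.asarray(freq_b, dtype=float)
    return 1.0 - p ** 2 - (1.0 - p) ** 2


def pic_biallelic(freq_b) -> np.ndarray:
    """Vectorized PIC for biallelic loci: GD - 2 p^2 (1-p)^2."""
    p = np.asarray(freq_b, dtype=float)
    return gene_diversity_biallelic(p) - 2.0 * (p * (1.0 - p)) ** 2


def _group_freq_b(matrix: GenotypeMatrix, line_index: np.ndarray) -> np.ndarray:
    """allele_b frequency per SNP within a subset of lines (NaN if no calls)."""
    d = matrix.calls[line_index]
    called = d >= 0
    n_alleles = 2 * called.sum(axis=0)
    count_b = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, count_b / n_alleles, np.nan)


def group_diversity_table(matrix: GenotypeMatrix, smap: SnpMap,
                          groups: Mapping[str, str] | pd.Series,
                          params: DiversityParams | None = None) -> pd.DataFrame:
    """Per-group diversity summary: n_lines and mean/min/max GD and PIC over SNPs.

    Allele frequencies are recomputed within each group's lines only.
    Groups with fewer than 2 lines are skipped with a warning.  SNPs with no
    calls in a group are excluded from that group's summary.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    params = params or DiversityParams()
    rows = []
    for label in groups.unique():
        members = groups.index[groups == label]
        idx = np.array([matrix.line_index(m) for m in members])
        if len(idx) < 2:
            warnings.warn(f"group {label!r} has {len(idx)} line(s); skipped")
            continue
        p = _group_freq_b(matrix, idx)
        gd = gene_diversity_biallelic(p)
        if params.apply_correction:
            denom = 1.0 - (1.0 + params.inbreeding_f) / len(idx)
            if denom <= 0:
                raise DomainError("correction denominator <= 0 for group " + label)
            gd = gd / denom
        pc = pic_biallelic(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append({
                "group": label, "n_lines": len(idx),
                "gd_mean": np.nanmean(gd), "gd_min": np.nanmin(gd), "gd_max": np.nanmax(gd),
                "pic_mean": np.nanmean(pc), "pic_min": np.nanmin(pc), "pic_max": np.nanmax(pc),
            })
    return pd.DataFrame(rows)


def binned_scan(smap: SnpMap, per_snp_values, bin_spec: BinSpec | None = None) -> pd.DataFrame:
    """Mean of a per-SNP statistic in each bin; bins with too few SNPs dropped."""
    return aggregate_by_bin(smap, per_snp_values, bin_spec or BinSpec())


def call_hotspots(scans_by_panel: Mapping[str, pd.DataFrame],
                  low_cutoff: float = 0.25, high_cutoff: float = 0.40) -> pd.DataFrame:
    """Flag low/high-diversity bins per panel and their common intersection.

    A bin is a low hotspot where the statistic is strictly below
    ``low_cutoff`` and a high hotspot where strictly above ``high_cutoff``
    (ties at the cutoffs are not hotspots).  The common flag marks bins
    carrying the same hotspot flag in every supplied panel.
    """
    if not scans_by_panel:
        raise ContractError("at least one scan is required")
    scans = dict(scans_by_panel)
    check_same_grid(scans)
    first = next(iter(scans.values()))
    out = first[["chromosome", "bin_index", "bin_start_bp", "bin_end_bp"]].copy()
    flags = []
    for name, scan in scans.items():
        stat = scan["statistic"].to_numpy()
        flag = np.full(len(scan), "none", dtype=object)
        with np.errstate(invalid="ignore"):
            flag[stat < low_cutoff] = "low_hotspot"
            flag[stat > high_cutoff] = "high_hotspot"
        flag[scan["flag"].to_numpy() == "dropped"] = "dropped"
        out[f"flag_{name}"] = flag
        flags.append(flag)
    flags = np.array(flags)
    common = np.full(len(out), "none", dtype=object)
    same = (flags == flags[0]).all(axis=0)
    hotspot = np.isin(flags[0], ("low_hotspot", "high_hotspot"))
    common[same & hotspot] = flags[0][same & hotspot]
    out["common"] = common
    return out
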