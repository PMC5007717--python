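"""Genomic binning shared by the diversity, divergence and relatedness scans.

Bins are half-open 0-based intervals [k*size, (k+1)*size) tiling each
chromosome from its start; a 1-based physical position p falls in bin
(p - 1) // size.  A bin labelled "130 Mb" is the bin starting at
130,000,000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import SnpMap, chromosome_sort_key


@dataclass(frozen=True)
class BinSpec:
    """Bin width and the minimum SNP count below which a bin is dropped."""

    bin_size_bp: int = 10_000_000
    min_snps_per_bin: int = 30

    def __post_init__(self):
        if self.bin_size_bp <= 0:
            raise ContractError("bin_size_bp must be positive")
        if self.min_snps_per_bin < 1:
            raise ContractError("min_snps_per_bin must be >= 1")


def bin_assignments(smap: SnpMap, bin_spec: BinSpec) -> pd.DataFrame:
    """Per placed SNP: chromosome and bin index.  Unplaced SNPs are excluded."""
    placed = smap.placed
    return pd.DataFrame(
        {
            "snp_index": np.flatnonzero(placed),
            "chromosome": smap.chromosome[placed],
            "bin_index": (smap.position_bp[placed] - 1) // bin_spec.bin_size_bp,
        }
    )


def bin_grid(smap: SnpMap, bin_spec: BinSpec) -> pd.DataFrame:
    """Full tiling: every bin from 0 up to the last SNP-bearing bin per chromosome."""
    asg = bin_assignments(smap, bin_spec)
    rows = []
    chroms = sorted(set(asg["chromosome"]), key=chromosome_sort_key)
    for chrom in chroms:
        last = int(asg.loc[asg["chromosome"] == chrom, "bin_index"].max())
        for k in range(last + 1):
            rows.append((chrom, k, k * bin_spec.bin_size_bp, (k + 1) * bin_spec.bin_size_bp))
    return pd.DataFrame(rows, columns=["chromosome", "bin_index", "bin_start_bp", "bin_end_bp"])


def aggregate_by_bin(smap: SnpMap, values: np.ndarray, bin_spec: BinSpec,
                     reducer="mean") -> pd.DataFrame:
    """Mean (or sum) of a per-SNP statistic within each bin.

    ``values`` is aligned to the map; NaN entries are excluded from both the
    SNP count and the statistic.  Returns one row per bin of the full grid
    with columns n_snps, statistic and flag (``dropped`` iff
    n_snps < min_snps_per_bin, in which case statistic is NaN).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(smap):
        raise ContractError("per-SNP values are not aligned to the map")
    asg = bin_assignments(smap, bin_spec)
    v = values[asg["snp_index"].to_numpy()]
    asg = asg.assign(value=v).dropna(subset=["value"])
    agg = asg.groupby(["chromosome", "bin_index"])["value"].agg(["size", reducer])
    grid = bin_grid(smap, bin_spec).set_index(["chromosome", "bin_index"])
    grid["n_snps"] = agg["size"].reindex(grid.index).fillna(0).astype(int)
    grid["statistic"] = agg[reducer].reindex(grid.index)
    dropped = grid["n_snps"] < bin_spec.min_snps_per_bin
    grid.loc[dropped, "statistic"] = np.nan
    grid["flag"] = np.where(dropped, "dropped", "none")
    return grid.reset_index()[
        ["chromosome", "bin_index", "bin_start_bp", "bin_end_bp", "n_snps", "statistic", "flag"]
    ]


def check_same_grid(scans: dict) -> None:
    """Contract check: all scans tile the same (chromosome, bin) grid."""
    keys = None
    for name, scan in scans.items():
        k = list(zip(scan["chromosome"], scan["bin_start_bp"], scan["bin_end_bp"]))
        if keys is None:
            keys = k
        elif k != keys:
            raise ContractError(f"scan {name!r} uses a different bin grid")
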