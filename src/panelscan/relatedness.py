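"""Identity-by-state similarity, conserved-segment detection and the
VanRaden genomic relationship matrix.

A SNP scores 1 for a pair of lines iff both calls are non-missing and
identical as unordered genotypes (het matches het only); the similarity
ratio divides the match count by the number of SNPs called in both lines
(``denominator="joint"``, the default) or by the fixed panel SNP total
(``denominator="total"``, the literal reading).

The kinship matrix is VanRaden's first method:

    K = Z Z' / (2 sum_k p_k (1 - p_k))

with Z the dosage matrix column-centred by 2 p_k, p_k the panel allele_b
frequency, missing dosages mean-imputed (centred to zero), and
monomorphic SNPs excluded from both numerator and denominator.  Negative
off-diagonals are clipped to zero only in the distribution report, never
in the stored matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._bins import BinSpec, bin_grid
from .errors import ContractError, DomainError
from .io import GenotypeMatrix, SnpMap

__all__ = [
    "SimilarityResult", "similarity_ratio", "similarity_matrix",
    "most_similar_lines", "binned_similarity", "BinnedSimilarity",
    "conserved_regions", "vanraden_kinship", "kinship_distribution",
]


@dataclass(frozen=True)
class SimilarityResult:
    line_i: str
    line_j: str
    n_compared: int
    n_matching: int

    @property
    def similarity_ratio(self) -> float:
        if self.n_compared == 0:
            return float("nan")
        return self.n_matching / self.n_compared


def similarity_ratio(calls_i, calls_j, line_i: str = "i", line_j: str = "j",
                     denominator: str = "joint") -> SimilarityResult:
    """IBS similarity between two aligned call vectors."""
    ci = np.asarray(calls_i)
    cj = np.asarray(calls_j)
    if ci.shape != cj.shape:
        raise ContractError("call vectors are not aligned")
    both = (ci >= 0) & (cj >= 0)
    matching = int((both & (ci == cj)).sum())
    n_compared = int(both.sum()) if denominator == "joint" else int(ci.size)
    return SimilarityResult(line_i, line_j, n_compared, matching)


def _match_and_joint_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise match counts and jointly-called counts via indicator products."""
    called = (calls >= 0).astype(float)
    joint = called @ called.T
    match = np.zeros_like(joint)
    for state in (0, 1, 2):
        ind = (calls == state).astype(float)
        match += ind @ ind.T
    return match, joint


def similarity_matrix(matrix: GenotypeMatrix,
                      denominator: str = "joint") -> tuple[pd.DataFrame, dict]:
    """All pairwise similarity ratios plus an extremes report.

    Returns (square DataFrame indexed by line ids, report dict with the
    off-diagonal mean and the max/min pairs).
    """
    if matrix.n_lines < 2:
        raise ContractError("similarity requires at least 2 lines")
    if denominator not in ("joint", "total"):
        raise ContractError("denominator must be 'joint' or 'total'")
    match, joint = _match_and_joint_counts(matrix.calls)
    denom = joint if denominator == "joint" else np.full_like(joint, matrix.n_snps)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, match / denom, np.nan)
    df = pd.DataFrame(sim, index=matrix.line_ids, columns=matrix.line_ids)
    iu, ju = np.triu_indices(matrix.n_lines, k=1)
    vals = sim[iu, ju]
    finite = np.isfinite(vals)
    report = {"mean": float(np.nanmean(vals)) if finite.any() else float("nan")}
    if finite.any():
        hi = np.flatnonzero(finite)[np.argmax(vals[finite])]
        lo = np.flatnonzero(finite)[np.argmin(vals[finite])]
        report["max_pair"] = (matrix.line_ids[iu[hi]], matrix.line_ids[ju[hi]],
                              float(vals[hi]))
        report["min_pair"] = (matrix.line_ids[iu[lo]], matrix.line_ids[ju[lo]],
                              float(vals[lo]))
    return df, report


def most_similar_lines(similarities: pd.DataFrame, focal_line: str,
                       k: int = 30) -> pd.DataFrame:
    """The k lines most similar to a focal line, descending.

    Ties are broken by line id ascending; k at or above the panel size
    returns all other lines.
    """
    if focal_line not in similarities.index:
        raise ContractError(f"focal line {focal_line!r} not in similarity matrix")
    s = similarities.loc[focal_line].drop(labels=[focal_line])
    out = (s.rename("similarity").rename_axis("line_id").reset_index()
           .sort_values(["similarity", "line_id"], ascending=[False, True],
                        kind="stable"))
    return out.head(min(k, len(out))).reset_index(drop=True)


@dataclass
class BinnedSimilarity:
    """Per-line-per-bin similarity to a focal line plus subset summaries."""

    per_line: pd.DataFrame       # chromosome, bin, line_id, n_compared, similarity
    per_bin: pd.DataFrame        # bin grid + n_snps, mean_similarity, flag
    per_chromosome: pd.DataFrame  # chromosome, mean_similarity


def binned_similarity(matrix: GenotypeMatrix, smap: SnpMap, focal_line: str,
                      subset, bin_spec: BinSpec | None = None) -> BinnedSimilarity:
    """Similarity of each subset line to the focal line restricted to each bin.

    The per-bin subset mean averages the defined per-line ratios; bins with
    fewer placed SNPs than the BinSpec minimum are flagged dropped.
    """
    bin_spec = bin_spec or BinSpec()
    subset = list(subset)
    if not subset:
        raise ContractError("subset is empty")
    focal_idx = matrix.line_index(focal_line)
    sub_idx = np.array([matrix.line_index(l) for l in subset])
    grid = bin_grid(smap, bin_spec)
    placed = smap.placed
    chrom = smap.chromosome
    binidx = np.where(placed, (smap.position_bp - 1) // bin_spec.bin_size_bp, -1)

    focal = matrix.calls[focal_idx]
    rows = []
    bin_rows = []
    for _, g in grid.iterrows():
        in_bin = placed & (chrom == g["chromosome"]) & (binidx == g["bin_index"])
        n_snps = int(in_bin.sum())
        sims = []
        for lid, li in zip(subset, sub_idx):
            res = similarity_ratio(focal[in_bin], matrix.calls[li][in_bin],
                                   focal_line, lid)
            ratio = res.similarity_ratio
            rows.append((g["chromosome"], int(g["bin_index"]), int(g["bin_start_bp"]),
                         int(g["bin_end_bp"]), lid, res.n_compared, ratio))
            if np.isfinite(ratio):
                sims.append(ratio)
        dropped = n_snps < bin_spec.min_snps_per_bin
        mean = float(np.mean(sims)) if sims and not dropped else np.nan
        bin_rows.append((g["chromosome"], int(g["bin_index"]), int(g["bin_start_bp"]),
                         int(g["bin_end_bp"]), n_snps, mean,
                         "dropped" if dropped else "none"))
    per_line = pd.DataFrame(rows, columns=["chromosome", "bin_index", "bin_start_bp",
                                           "bin_end_bp", "line_id", "n_compared",
                                           "similarity"])
    per_bin = pd.DataFrame(bin_rows, columns=["chromosome", "bin_index", "bin_start_bp",
                                              "bin_end_bp", "n_snps", "mean_similarity",
                                              "flag"])
    per_chrom = (per_line.dropna(subset=["similarity"])
                 .groupby("chromosome", sort=False)["similarity"].mean()
                 .rename("mean_similarity").reset_index())
    return BinnedSimilarity(per_line=per_line, per_bin=per_bin, per_chromosome=per_chrom)


def conserved_regions(per_bin: pd.DataFrame, threshold: float = 0.85) -> pd.DataFrame:
    """Maximal runs of adjacent non-dropped bins with mean similarity > threshold.

    Runs are broken by dropped bins and by bins at or below the threshold;
    regions are reported per chromosome with their bin span, SNP count and
    the unweighted mean of bin means.
    """
    regions = []
    for chrom, g in per_bin.groupby("chromosome", sort=False):
        g = g.sort_values("bin_index")
        run = []
        def flush(run):
            if run:
                regions.append({
                    "chromosome": chrom,
                    "start_bin": int(run[0]["bin_index"]),
                    "end_bin": int(run[-1]["bin_index"]),
                    "bin_start_bp": int(run[0]["bin_start_bp"]),
                    "bin_end_bp": int(run[-1]["bin_end_bp"]),
                    "n_bins": len(run),
                    "n_snps": int(sum(r["n_snps"] for r in run)),
                    "mean_similarity": float(np.mean([r["mean_similarity"] for r in run])),
                })
        prev_bin = None
        for _, row in g.iterrows():
            ok = (row["flag"] != "dropped" and np.isfinite(row["mean_similarity"])
                  and row["mean_similarity"] > threshold)
            contiguous = prev_bin is not None and row["bin_index"] == prev_bin + 1
            if ok and (not run or contiguous):
                run.append(row)
            elif ok:
                flush(run)
                run = [row]
            else:
                flush(run)
                run = []
            prev_bin = row["bin_index"]
        flush(run)
    return pd.DataFrame(regions, columns=["chromosome", "start_bin", "end_bin",
                                          "bin_start_bp", "bin_end_bp", "n_bins",
                                          "n_snps", "mean_similarity"])


def vanraden_kinship(matrix: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix from panel dosages."""
    d = matrix.dosage_float()
    p = np.nanmean(d, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise DomainError("all SNPs monomorphic (or uncalled); kinship undefined")
    d = d[:, poly]
    p = p[poly]
    z = d - 2.0 * p
    z[~np.isfinite(z)] = 0.0  # mean imputation: missing centred dosage = 0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    k = (z @ z.T) / denom
    return pd.DataFrame(k, index=matrix.line_ids, columns=matrix.line_ids)


def kinship_distribution(kinship: pd.DataFrame, bin_width: float = 0.05,
                         clip_negative: bool = True) -> dict:
    """Histogram summary of off-diagonal kinship coefficients.

    With clipping on, negative estimates are set to zero before counting,
    and ``fraction_zero`` is the mass exactly at zero after clipping.
    Histogram counts over [0, max] with the stated bin width sum to the
    number of unordered pairs.
    """
    k = kinship.to_numpy()
    iu, ju = np.triu_indices(k.shape[0], k=1)
    vals = k[iu, ju].copy()
    if clip_negative:
        vals = np.clip(vals, 0.0, None)
    n_pairs = len(vals)
    fraction_zero = float((vals == 0.0).sum() / n_pairs) if n_pairs else float("nan")
    top = max(float(vals.max()), bin_width) if n_pairs else bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    hist = pd.DataFrame({
        "lower": edges[:-1], "upper": edges[1:], "count": counts,
        "fraction": counts / n_pairs if n_pairs else np.nan,
    })
    return {"n_pairs": n_pairs, "fraction_zero": fraction_zero, "histogram": hist}
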