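"""Linkage disequilibrium: pairwise r-squared, distance-binned decay profiles
and the interval-based decay distance.

r2 between two SNPs is the squared Pearson correlation of their allele_b
dosage vectors over the lines non-missing at both SNPs (composite / dosage
LD; no phasing).  For near-fully-inbred lines this coincides with the
haplotype definition almost exactly.  Pairs whose jointly-called subset is
monomorphic at either SNP have undefined r2 and are skipped (tallied).

The decay distance is reported as the lowest-distance interval of the
profile grid whose mean r2 falls below the cutoff (0.1); if no interval
falls below, the profile decays "beyond grid".  The default grid is the
union of all interval bounds used when reporting decay by group and
chromosome: [0, 0.1), [0.1, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1),
[1, 1.5), [1.5, 2), [2, 2.5), [2.5, 3), [3, 3.5), [3.5, 4), [4, 5),
[5, 10), [10, inf) Mb.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import GenotypeMatrix, SnpMap, chromosome_sort_key

logger = logging.getLogger(__name__)

_MB = 1_000_000
#: default distance-interval bounds in bp (half-open, ascending)
DEFAULT_GRID_BP: tuple = (
    0, int(0.1 * _MB), int(0.25 * _MB), int(0.5 * _MB), int(0.75 * _MB),
    1 * _MB, int(1.5 * _MB), 2 * _MB, int(2.5 * _MB), 3 * _MB,
    int(3.5 * _MB), 4 * _MB, 5 * _MB, 10 * _MB, np.inf,
)

_VAR_EPS = 1e-12


@dataclass
class LdDecayProfile:
    """Distance-interval grid with mean r2 per interval and the decay interval.

    ``decay_interval`` is the (lower, upper) bp bounds of the first interval
    whose mean r2 is below the cutoff, or None when the profile stays at or
    above the cutoff across the grid ("beyond grid").
    """

    table: pd.DataFrame
    decay_interval: tuple | None
    cutoff: float = 0.1

    @property
    def beyond_grid(self) -> bool:
        return self.decay_interval is None


def pairwise_r2(matrix: GenotypeMatrix, smap: SnpMap, chromosome: str,
                max_distance_bp: float = 50_000_000,
                lines=None) -> pd.DataFrame:
    """All intrachromosomal SNP pairs within ``max_distance_bp`` and their r2.

    ``lines`` optionally restricts the panel (list of line ids).  Returns a
    DataFrame (snp_i, snp_j, distance_bp, r2, n_lines); pairs undefined
    because of joint monomorphism are skipped and tallied in
    ``df.attrs["n_skipped_monomorphic"]``.
    """
    sel = np.flatnonzero((smap.chromosome == str(chromosome)) & smap.placed)
    if len(sel) < 2:
        raise ContractError(f"chromosome {chromosome!r} has fewer than 2 placed SNPs")
    order = sel[np.argsort(smap.position_bp[sel], kind="stable")]
    pos = smap.position_bp[order]
    ids = smap.snp_id[order]
    if lines is not None:
        rows = np.array([matrix.line_index(l) for l in lines])
    else:
        rows = np.arange(matrix.n_lines)
    d = matrix.calls[np.ix_(rows, order)].astype(float)
    called = d >= 0
    d0 = np.where(called, d, 0.0)
    m = called.astype(float)

    n = m.T @ m
    sx = d0.T @ m          # sx[i, j] = sum of x_i over lines called at both
    sxy = d0.T @ d0
    sxx = (d0 * d0).T @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_i = sxx - sx ** 2 / n
        var_j = var_i.T
        r2 = cov ** 2 / (var_i * var_j)

    s = len(order)
    iu, ju = np.triu_indices(s, k=1)
    dist = np.abs(pos[ju] - pos[iu])
    within = dist <= max_distance_bp
    iu, ju, dist = iu[within], ju[within], dist[within]
    defined = (var_i[iu, ju] > _VAR_EPS) & (var_j[iu, ju] > _VAR_EPS) & (n[iu, ju] >= 2)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.debug("chromosome %s: %d pair(s) skipped (monomorphic in joint subset)",
                     chromosome, n_skipped)
    iu, ju, dist = iu[defined], ju[defined], dist[defined]
    out = pd.DataFrame({
        "snp_i": ids[iu],
        "snp_j": ids[ju],
        "distance_bp": dist,
        "r2": np.clip(r2[iu, ju], 0.0, 1.0),
        "n_lines": n[iu, ju].astype(int),
    })
    out.attrs["n_skipped_monomorphic"] = n_skipped
    return out


def decay_profile(pairs: pd.DataFrame, grid=None, cutoff: float = 0.1) -> LdDecayProfile:
    """Mean r2 per distance interval and the first interval below the cutoff.

    Empty intervals (zero pairs) have undefined means and are skipped in
    the decay scan with a logged note.
    """
    if len(pairs) == 0:
        raise ContractError("no LD pairs supplied")
    grid = np.asarray(DEFAULT_GRID_BP if grid is None else grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ContractError("interval grid bounds must be strictly ascending")
    dist = pairs["distance_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    which = np.searchsorted(grid, dist, side="right") - 1
    rows = []
    decay = None
    for k in range(len(grid) - 1):
        in_k = which == k
        n_pairs = int(in_k.sum())
        mean = float(r2[in_k].mean()) if n_pairs else np.nan
        rows.append((grid[k], grid[k + 1], n_pairs, mean))
        if n_pairs == 0:
            logger.debug("interval [%s, %s) has no pairs; skipped in decay scan",
                         grid[k], grid[k + 1])
        elif decay is None and mean < cutoff:
            decay = (grid[k], grid[k + 1])
    table = pd.DataFrame(rows, columns=["lower_bp", "upper_bp", "n_pairs", "mean_r2"])
    return LdDecayProfile(table=table, decay_interval=decay, cutoff=cutoff)


def decay_by_panel_and_chromosome(matrix: GenotypeMatrix, smap: SnpMap,
                                  groups: pd.Series, grid=None,
                                  max_distance_bp: float = 50_000_000,
                                  cutoff: float = 0.1,
                                  exclude_labels=("Mixed",),
                                  min_group_size: int = 10) -> pd.DataFrame:
    """Decay-interval table: (entire panel + each group) x (chromosome + total).

    Groups in ``exclude_labels`` are left out; groups smaller than
    ``min_group_size`` are computed anyway with a warning.
    """
    groups = pd.Series(groups)
    panels = {"entire": None}
    for label in groups.unique():
        if label in exclude_labels:
            continue
        members = list(groups.index[groups == label])
        if len(members) < min_group_size:
            warnings.warn(f"group {label!r} has only {len(members)} lines")
        panels[label] = members
    chroms = sorted({c for c in smap.chromosome[smap.placed]}, key=chromosome_sort_key)
    rows = []
    for panel, members in panels.items():
        pooled = []
        for chrom in chroms:
            pairs = pairwise_r2(matrix, smap, chrom, max_distance_bp, lines=members)
            pooled.append(pairs)
            prof = decay_profile(pairs, grid=grid, cutoff=cutoff)
            lo, hi = prof.decay_interval if prof.decay_interval else (np.nan, np.nan)
            rows.append((panel, chrom, len(pairs), lo, hi))
        prof = decay_profile(pd.concat(pooled, ignore_index=True), grid=grid, cutoff=cutoff)
        lo, hi = prof.decay_interval if prof.decay_interval else (np.nan, np.nan)
        rows.append((panel, "total", sum(len(p) for p in pooled), lo, hi))
    return pd.DataFrame(rows, columns=["panel", "chromosome", "n_pairs",
                                       "decay_lower_bp", "decay_upper_bp"])
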