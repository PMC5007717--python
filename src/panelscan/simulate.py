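"""Synthetic structured inbred panels with a known truth manifest.

The generator emulates the structure the genome scans assume: a
multi-group panel of near-fully-homozygous lines whose per-group allele
frequencies diverge from a shared ancestral frequency under the
Balding-Nichols F-model,

    p_group ~ Beta( p (1 - F) / F,  (1 - p) (1 - F) / F ),
    p ~ Uniform(0.05, 0.95),

with distance-decaying haplotype correlation within each group (a
first-order Gaussian-copula Markov process along sorted positions with
latent correlation exp(-d / lambda), so r2 decays monotonically with
distance at a group-specific scale), admixed lines, forced
allele-frequency gaps inside designated windows, and founder-derived
lines that copy a founder's calls inside a designated segment with a
per-SNP retention probability (and optionally at a low background rate
elsewhere, so derived lines are also globally more similar to the founder
than random group mates are).

All draws come from a single seeded generator: identical seed, identical
output.  The truth manifest records the generating frequencies, window
and segment coordinates, and line labels, so every downstream scan can be
checked against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .io import CALL_MISSING, GenotypeMatrix, SnpMap
from .structure_post import MIXED_LABEL

__all__ = [
    "GroupSpec", "DivergentWindow", "FounderSegment", "SimulationConfig",
    "TruthManifest", "PanelBundle", "simulate_panel", "emulate_paper_panel",
]


@dataclass(frozen=True)
class GroupSpec:
    """One panel group: size, divergence F from the ancestral pool and the
    LD correlation length (bp) of its haplotypes."""

    label: str
    n_lines: int
    divergence_f: float
    ld_lambda_bp: float


@dataclass(frozen=True)
class DivergentWindow:
    """Force an allele-frequency gap between the first two groups inside
    [start_bp, end_bp) (0-based half-open)."""

    chromosome: str
    start_bp: int
    end_bp: int
    freq_gap: float


@dataclass(frozen=True)
class FounderSegment:
    """Copy a founder's calls into derived lines inside [start_bp, end_bp)
    with per-SNP probability ``retention`` (and ``background_retention``
    outside the segment)."""

    founder: str
    n_derived: int
    chromosome: str
    start_bp: int
    end_bp: int
    retention: float
    background_retention: float = 0.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 10
    chromosome_length_bp: int = 150_000_000
    n_snps: int = 5_000
    groups: list = field(default_factory=list)
    n_admixed_lines: int = 0
    admixture_proportions: tuple | None = None
    residual_het_rate: float = 0.02
    missing_rate: float = 0.01
    divergent_windows: list = field(default_factory=list)
    founder_segments: list = field(default_factory=list)
    maf_floor: float = 0.05
    ascertainment_group: str | None = None

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group is required")
        for g in self.groups:
            if g.n_lines < 2:
                raise ConfigError(f"group {g.label!r} must have >= 2 lines")
            if not (0.0 < g.divergence_f < 1.0):
                raise ConfigError(f"group {g.label!r}: divergence F must be in (0, 1)")
        for r in (self.residual_het_rate, self.missing_rate, self.maf_floor):
            if not (0.0 <= r <= 1.0):
                raise ConfigError("rates must lie in [0, 1]")
        for w in self.divergent_windows:
            if w.freq_gap > 1.0 or w.freq_gap < 0.0:
                raise ConfigError(f"infeasible frequency gap {w.freq_gap}")
            if not (0 <= w.start_bp < w.end_bp <= self.chromosome_length_bp):
                raise ConfigError("divergent window outside chromosome bounds")
        for s in self.founder_segments:
            if not (0 <= s.start_bp < s.end_bp <= self.chromosome_length_bp):
                raise ConfigError("founder segment outside chromosome bounds")
            if not (0.0 <= s.retention <= 1.0 and 0.0 <= s.background_retention <= 1.0):
                raise ConfigError("retention probabilities must lie in [0, 1]")


@dataclass
class TruthManifest:
    """Generating parameters of an emitted panel, aligned to its SNP map."""

    ancestral_freq: np.ndarray
    group_freqs: dict           # label -> per-SNP allele_b frequency array
    line_groups: dict           # line_id -> label ("Mixed" for admixed)
    windows: list               # DivergentWindow
    segments: list              # dict: FounderSegment fields + derived line ids
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "ancestral_freq": np.round(self.ancestral_freq, 6).tolist(),
            "group_freqs": {k: np.round(v, 6).tolist() for k, v in self.group_freqs.items()},
            "line_groups": self.line_groups,
            "windows": [asdict(w) for w in self.windows],
            "segments": self.segments,
            "config": {**asdict(self.config),
                       "groups": [asdict(g) for g in self.config.groups],
                       "divergent_windows": [asdict(w) for w in self.config.divergent_windows],
                       "founder_segments": [asdict(s) for s in self.config.founder_segments]},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class PanelBundle:
    config: SimulationConfig
    snp_map: SnpMap
    genotypes: GenotypeMatrix
    groups: pd.Series
    manifest: TruthManifest


def _markov_haplotypes(rng, freqs, positions, lam, n_lines) -> np.ndarray:
    """Inbred haplotypes with distance-decaying correlation.

    A latent AR(1) Gaussian process along the chromosome (correlation
    exp(-d / lam) between adjacent SNPs) is thresholded at the per-SNP
    allele frequency, giving Bernoulli(p_k) marginals with spatially
    decaying dependence.  Returns an (n_lines, n_snps) 0/1 allele matrix.
    """
    m = len(freqs)
    z = np.empty((n_lines, m))
    z[:, 0] = rng.standard_normal(n_lines)
    if m > 1:
        rho = np.exp(-np.diff(positions) / lam)
        noise = rng.standard_normal((n_lines, m - 1))
        scale = np.sqrt(1.0 - rho ** 2)
        for k in range(1, m):
            z[:, k] = rho[k - 1] * z[:, k - 1] + scale[k - 1] * noise[:, k - 1]
    return (z < norm.ppf(freqs)[None, :]).astype(np.int8)


def simulate_panel(config: SimulationConfig
                   ) -> tuple[SnpMap, GenotypeMatrix, pd.Series, TruthManifest]:
    """Generate a structured panel plus its truth manifest (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # SNP map: equal expected counts per chromosome, uniform unique positions
    per_chrom = rng.multinomial(config.n_snps, np.full(config.n_chromosomes,
                                                       1.0 / config.n_chromosomes))
    chroms, positions = [], []
    for c, m in enumerate(per_chrom, start=1):
        pos = np.unique(rng.integers(1, config.chromosome_length_bp + 1, size=m))
        while len(pos) < m:  # rare collision top-up
            extra = rng.integers(1, config.chromosome_length_bp + 1, size=m - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.append(np.full(m, str(c), dtype=object))
        positions.append(np.sort(pos))
    chrom_labels = [str(c) for c in range(1, config.n_chromosomes + 1)]
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    n_snps = len(pos_arr)
    allele_pairs = np.array([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")],
                            dtype=object)
    pair_idx = rng.integers(0, len(allele_pairs), size=n_snps)
    smap = SnpMap(pd.DataFrame({
        "snp_id": [f"SNP_{c}_{i:05d}" for i, c in enumerate(chrom_arr)],
        "chromosome": chrom_arr,
        "position_bp": pos_arr,
        "allele_a": allele_pairs[pair_idx, 0],
        "allele_b": allele_pairs[pair_idx, 1],
    }))

    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    group_freqs = {}
    for g in config.groups:
        f = g.divergence_f
        a = ancestral * (1.0 - f) / f
        b = (1.0 - ancestral) * (1.0 - f) / f
        group_freqs[g.label] = rng.beta(a, b)

    # forced frequency gaps between the first two groups
    for w in config.divergent_windows:
        in_w = ((chrom_arr == w.chromosome)
                & (pos_arr - 1 >= w.start_bp) & (pos_arr - 1 < w.end_bp))
        if len(config.groups) < 2:
            raise ConfigError("divergent windows need at least two groups")
        g1, g2 = config.groups[0].label, config.groups[1].label
        group_freqs[g1][in_w] = 0.5 + w.freq_gap / 2.0
        group_freqs[g2][in_w] = 0.5 - w.freq_gap / 2.0

    # genotypes, chromosome by chromosome to respect the Markov structure
    line_ids, line_groups, blocks = [], {}, []
    for g in config.groups:
        ids = [f"{g.label}_{i:03d}" for i in range(g.n_lines)]
        line_ids.extend(ids)
        line_groups.update({i: g.label for i in ids})
        rows = []
        for c in chrom_labels:
            on_c = chrom_arr == c
            hap = _markov_haplotypes(rng, group_freqs[g.label][on_c],
                                     pos_arr[on_c].astype(float),
                                     g.ld_lambda_bp, g.n_lines)
            rows.append(2 * hap)  # fully inbred: one haplotype, doubled
        blocks.append(np.concatenate(rows, axis=1))
    if config.n_admixed_lines:
        props = config.admixture_proportions
        if props is None:
            props = tuple(1.0 / len(config.groups) for _ in config.groups)
        if len(props) != len(config.groups) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError("admixture proportions must match groups and sum to 1")
        p_mix = sum(w * group_freqs[g.label] for w, g in zip(props, config.groups))
        lam_mix = sum(w * g.ld_lambda_bp for w, g in zip(props, config.groups))
        ids = [f"MIX_{i:03d}" for i in range(config.n_admixed_lines)]
        line_ids.extend(ids)
        line_groups.update({i: MIXED_LABEL for i in ids})
        rows = []
        for c in chrom_labels:
            on_c = chrom_arr == c
            hap = _markov_haplotypes(rng, p_mix[on_c], pos_arr[on_c].astype(float),
                                     lam_mix, config.n_admixed_lines)
            rows.append(2 * hap)
        blocks.append(np.concatenate(rows, axis=1))
    calls = np.concatenate(blocks, axis=0).astype(np.int8)

    # residual heterozygosity, then missingness
    if config.residual_het_rate > 0:
        het = rng.random(calls.shape) < config.residual_het_rate
        calls[het] = 1
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = CALL_MISSING

    # founder-derived lines copy the founder's (noisy) calls
    segments = []
    index_of = {lid: i for i, lid in enumerate(line_ids)}
    for s in config.founder_segments:
        if s.founder not in index_of:
            raise ConfigError(f"founder {s.founder!r} is not a panel line")
        founder_row = index_of[s.founder]
        group = line_groups[s.founder]
        candidates = [l for l in line_ids
                      if line_groups[l] == group and l != s.founder]
        if len(candidates) < s.n_derived:
            raise ConfigError(f"group {group!r} too small for {s.n_derived} derived lines")
        derived = candidates[: s.n_derived]
        in_seg = ((chrom_arr == s.chromosome)
                  & (pos_arr - 1 >= s.start_bp) & (pos_arr - 1 < s.end_bp))
        prob = np.where(in_seg, s.retention, s.background_retention)
        for lid in derived:
            copy = rng.random(n_snps) < prob
            calls[index_of[lid], copy] = calls[founder_row, copy]
        segments.append({**asdict(s), "derived_lines": derived})

    # array-style ascertainment: panel MAF floor, optional group-monomorphism drop
    keep = np.ones(n_snps, dtype=bool)
    if config.maf_floor > 0:
        called = calls >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called.sum(0) > 0,
                            np.where(called, calls, 0).sum(0) / (2 * called.sum(0)), np.nan)
        maf = np.minimum(freq, 1 - freq)
        keep &= np.nan_to_num(maf) >= config.maf_floor
    if config.ascertainment_group is not None:
        rows = [index_of[l] for l, g in line_groups.items()
                if g == config.ascertainment_group]
        sub = calls[rows]
        called = sub >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called.sum(0) > 0,
                            np.where(called, sub, 0).sum(0) / (2 * called.sum(0)), np.nan)
        keep &= np.isfinite(freq) & (freq > 0) & (freq < 1)
    smap = smap.take(np.flatnonzero(keep))
    calls = calls[:, keep]

    manifest = TruthManifest(
        ancestral_freq=ancestral[keep],
        group_freqs={k: v[keep] for k, v in group_freqs.items()},
        line_groups=dict(line_groups),
        windows=list(config.divergent_windows),
        segments=segments,
        config=config,
    )
    groups = pd.Series(line_groups, name="group").loc[line_ids]
    return smap, GenotypeMatrix(line_ids, calls), groups, manifest


def emulate_paper_panel(seed: int, n_snps: int = 5_000) -> PanelBundle:
    """A ready-made reduced-scale panel mirroring the study's structure.

    Two groups (temperate-like, 150 lines; tropical-like, 130 lines) plus
    20 admixed lines across 10 chromosomes of 150 Mb; one forced
    high-divergence window in the bin starting at 130 Mb of chromosome 2;
    one tropical founder with 30 derived lines sharing the 30-120 Mb
    segment of chromosome 7 (retention 0.95, background retention 0.3);
    temperate-like LD correlation length 5x the tropical-like one.
    """
    config = SimulationConfig(
        seed=int(seed),
        n_chromosomes=10,
        chromosome_length_bp=150_000_000,
        n_snps=int(n_snps),
        groups=[
            GroupSpec("Temperate", 150, divergence_f=0.05, ld_lambda_bp=2_000_000),
            GroupSpec("Tropical", 130, divergence_f=0.05, ld_lambda_bp=400_000),
        ],
        n_admixed_lines=20,
        admixture_proportions=(0.5, 0.5),
        residual_het_rate=0.02,
        missing_rate=0.01,
        divergent_windows=[DivergentWindow("2", 130_000_000, 140_000_000, 0.8)],
        founder_segments=[FounderSegment(
            founder="Tropical_000", n_derived=30, chromosome="7",
            start_bp=30_000_000, end_bp=120_000_000,
            retention=0.95, background_retention=0.3,
        )],
        maf_floor=0.05,
    )
    smap, matrix, groups, manifest = simulate_panel(config)
    return PanelBundle(config, smap, matrix, groups, manifest)
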