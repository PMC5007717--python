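# Methods

## Data model

Genotypes are unphased biallelic calls for inbred lines: homozygous for
either allele, heterozygous (residual, since the lines are near-fully
selfed), or missing. The canonical in-memory encoding is the dosage of
the designated `allele_b` — 0, 1, 2, with −1 for missing — which makes
the call-state and dosage views coincide. `allele_b` is the second
allele of the HapMap `alleles` field; every statistic that is symmetric
in allele labels is verified (by test) to be invariant to this choice.
Physical positions are 1-based inclusive; all binning converts to
0-based half-open internally, so a 10-Mb bin labelled "130 Mb" covers
positions 130,000,001–140,000,000. Strand is ignored: array genotypes
are reported on a fixed strand and no reverse-complement reconciliation
is attempted. Duplicate line ids are a hard error — replicate-sample
merging belongs to the upstream genotype-calling step, and the package
assumes one consensus row per line.

## Estimators

**Gene diversity.** `GD = 1 − Σᵤ p̃ᵤ²`, the probability that two alleles
drawn at random differ. The finite-sample correction
`/(1 − (1+f)/n)` is available through `DiversityParams` but is off by
default: the biallelic ceiling of the uncorrected estimator is exactly
0.5 (and 0.375 for PIC), which the group summaries treat as the
attainable maxima, and the correction would push estimates past it.
Allele frequencies come from allele counts: a heterozygote contributes
one copy of each allele, a missing call nothing; an uncalled locus gets
NaN frequencies, never a division by zero.

**PIC.** `PIC = 1 − Σᵤ p̃ᵤ² − Σᵤ<ᵥ 2 p̃ᵤ² p̃ᵥ²`, computed via the identity
`Σᵤ<ᵥ 2 p̃ᵤ² p̃ᵥ² = (Σ p̃²)² − Σ p̃⁴`. For biallelic loci
`0 ≤ PIC ≤ GD ≤ 0.5`, equalities at monomorphism.

**QC boundaries.** The primary filter excludes strictly
(missing > 0.20, het > 0.20, MAF < 0.05), so boundary values are
retained; the structure subset keeps strictly (missing < 0.05,
GD > 0.45). The GD used for the subset is the uncorrected whole-panel
estimator, since that subset is selected once on the full panel.

**χ² divergence.** Pearson χ² without continuity correction, df = 1, on
the 2×2 table of allele copies per group, at a fixed per-SNP α = 0.001
with no multiple-testing correction (the scan reports a per-bin ratio,
not a family-wise claim). Tables with a zero marginal are untestable and
excluded from both numerator and denominator of binned ratios; expected
cell counts < 5 set an advisory flag but still compute. Allele rather
than genotype counts are used because the compared quantity is an allele
frequency; for near-fully-inbred lines the two are proportional anyway.

**Unique (private-allele) SNPs.** A SNP polymorphic in one group and
monomorphic in the other. By default it is credited to the *polymorphic*
group — the group that actually carries both alleles; the inverse
reading (credit the group in which an allele is absent) is available via
`credit="monomorphic"` since the verbal definition admits both.

**LD.** `r²` is the squared Pearson correlation of the two dosage
vectors over lines called at both SNPs (composite LD, no phasing): with
post-filter heterozygosity ≤ 20 % this coincides with haplotype `r²`
almost exactly, and no phasing information exists for array data on
inbreds. Pairs are capped at 50 Mb by default (configurable to ∞) —
decay decisions happen well below 10 Mb. The decay distance is the
first distance interval, ascending, whose mean `r²` drops below 0.1,
without requiring later intervals to stay below; empty intervals are
skipped with a log note, and a profile that never drops reports "beyond
grid". The default grid is the union of all interval bounds used in the
by-chromosome decay table: 0, 0.1, 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3,
3.5, 4, 5, 10 Mb, ∞.

**Similarity.** A SNP scores 1 for a pair iff both calls are present and
identical as unordered genotypes (het matches only het — no half-match
scheme). The default denominator is the count of SNPs called in *both*
lines; dividing by the fixed panel total (`denominator="total"`) is kept
as the literal variant, but it deflates ratios asymmetrically under
per-line missingness. Similarity never imputes.

**Conserved regions.** Per 10-Mb bin, the mean similarity of a focal
line to a chosen subset (typically its k = 30 most-similar lines, ties
broken by line id); maximal runs of adjacent non-dropped bins with mean
strictly above 0.85 are reported per chromosome. Dropped bins break
runs.

**Kinship.** VanRaden method 1: `K = ZZ′ / (2 Σₖ pₖ(1−pₖ))` with Z the
dosage matrix centred by `2pₖ` (panel frequency), missing dosages
mean-imputed (centred value 0) — for kinship only — and monomorphic SNPs
excluded from numerator and denominator. Negative off-diagonals are
clipped to zero only in the distribution report (that clipping is what
produces a point mass "exactly at zero"); the stored matrix keeps the
raw values for downstream modelling.

**Phylogeny.** Per-line allele "frequencies" at a locus are (1, 0),
(0.5, 0.5) or (0, 1) from that line's own genotype — leaves are lines,
so no group pooling. The default distance is Nei's 1972 standard
distance `D = −ln(Jxy/√(JxJy))` with J's averaged over loci called in
both lines; which variant the classical software meant is ambiguous, so
Nei's 1983 D_A is provided behind a flag. Lines sharing no alleles get
+∞ (the tree builder rejects non-finite input with a remediation hint to
filter loci). Neighbor joining is the standard Saitou–Nei Q-criterion
agglomeration, deterministic ties to the smallest (i, j) index pair;
negative branch-length estimates are floored at zero and logged. Newick
output quotes ids containing metacharacters.

**Evanno ΔK.** `ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| /
sd(L(K))` over replicate log-likelihoods, sd with the n−1 denominator;
endpoints and zero-sd points are undefined with a note. Group
assignment takes the component with the maximal membership coefficient
iff it reaches the threshold, else "Mixed". The default threshold is
0.6 — a conventional admixture cut; the original pedigree-informed
per-group thresholds are not published, so every run records the
threshold used. The admixture MCMC itself is out of scope: only its
tabular outputs are consumed.

## Synthetic panel generator

The generator produces the structure the scans assume, with a manifest
of every generating parameter:

* **Group frequencies** follow the Balding–Nichols F-model:
  `p_group ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` around an ancestral
  `p ~ U(0.05, 0.95)`. This is the minimal standard model producing
  two-group frequency structure; no claim of coalescent realism.
* **LD** is induced at the haplotype level by a first-order
  Gaussian-copula Markov process along sorted positions: a latent AR(1)
  with correlation `exp(−d/λ)` between adjacent SNPs, thresholded at
  each SNP's group frequency. This gives monotone r²–distance decay at a
  group-specific scale λ and is cheap at desk scale; it does not model
  recombination hotspots or coalescent genealogies.
* **Lines** are fully inbred (one haplotype, doubled), then perturbed by
  a residual heterozygosity rate (default 0.02) and a missing rate
  (default 0.01) — values typical of cleaned array data on inbreds.
* **Divergent windows** override the first two groups' frequencies to
  `0.5 ± gap/2` inside the window, forcing the stated |Δp|.
* **Founder segments** copy the founder's (noisy) calls into derived
  lines with per-SNP retention probability inside the window, so
  retention 1.0 makes derived lines bin-identical to the founder. A low
  `background_retention` outside the segment makes derived lines
  globally more similar to the founder than random group mates — the
  pattern real founder-derived material shows — which is what lets
  top-k-by-similarity selection recover them.
* **Ascertainment**: a post-hoc panel MAF floor (default 0.05) mimics
  array SNP selection; an optional mode additionally drops SNPs
  monomorphic in a designated group, emulating discovery-panel bias.

All draws come from one `numpy` generator seeded by the config: same
seed, byte-identical panel.

### The study-mirroring preset

`emulate_paper_panel(seed)` instantiates a reduced-scale two-group
panel: 150 temperate-like and 130 tropical-like lines plus 20 admixed
(50/50) lines; 10 chromosomes × 150 Mb; 5,000 SNPs before the MAF floor
(~4,800 after); per-group divergence F = 0.05 (a typical temperate vs
tropical differentiation scale); λ_temperate = 2.0 Mb = 5 ×
λ_tropical = 0.4 Mb; one divergent window (gap 0.8) at 130–140 Mb of
chromosome 2; one tropical founder with 30 derived lines sharing
30–120 Mb of chromosome 7 at retention 0.95 (background 0.3).

**Scaled bin-drop rule.** The full-density rule — drop 10-Mb bins with
fewer than 30 SNPs — was calibrated for ~200 SNPs expected per bin. The
emulated panel carries ~33 expected per bin, so analyses on it scale the
rule proportionally to a minimum of 5 SNPs per bin (the same ≈1/7 of
expectation); the library default `BinSpec` keeps 30. This is a problem-
size choice for desk-scale work, stated here once and used everywhere
the emulated panel is scanned.

## What passing tests do and do not show

The generator reproduces the *relational* structure of a real panel —
group divergence, decaying LD, planted windows and segments with known
coordinates — so tests demonstrate that each scan recovers what was
planted and that every estimator agrees with an independent
recomputation. It does not reproduce dataset-dependent magnitudes of
any particular germplasm collection (post-filter SNP counts, exact group
GD means, unique-SNP counts, kinship zero-mass): those depend on the
actual genotype matrix and are not claims this package can verify from
synthetic data. Recovery checks on the emulated panel show method
correctness at realistic signal sizes, not field performance on any
specific collection.

## Numerical choices and degenerate inputs

* Allele-frequency vectors must sum to 1 within 1e-9; the corrected GD
  denominator must be positive (else a domain error).
* r² pairs with variance ≤ 1e-12 in the joint-complete subset are
  skipped and tallied, never reported as 0/0.
* All-missing loci, empty groups at a SNP, and zero-marginal χ² tables
  carry NaN/untestable sentinels and are excluded from aggregates with
  logged counts.
* Hotspot and conserved-region cutoffs are strict inequalities; ties at
  a cutoff are not calls.
* Kinship histogram bins are half-open `[k·w, (k+1)·w)` of width 0.05;
  the exact-zero mass is reported separately from the histogram.
* NJ tie-breaks: smallest (i, j) pair in current matrix order; branch
  lengths floored at 0 with a log note.

## Known limitations

* Composite (dosage) r² understates haplotype r² when heterozygosity is
  appreciable; acceptable here because inputs are inbred panels.
* The Markov LD model has a single correlation length per group — no
  recombination-rate variation along chromosomes, so centromeric LD
  structure is not emulated (centromere proximity is carried as optional
  reporting metadata only; no statistic depends on it).
* Nei-distance +∞ sentinels require locus filtering before tree
  building; the package deliberately does not silently drop such pairs.
* The admixture model itself (Bayesian MCMC), replicate label alignment
  across runs, PCA ordination, and graphical rendering of trees and heat
  maps are out of scope; the package computes the tables those tools
  consume or post-processes the outputs they produce.
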