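# panelscan

Characterization of SNP genotype panels of inbred breeding lines —
the analysis chain a maize (or other selfing-crop) breeding program runs
on an array-genotyped germplasm collection to understand its heterotic
groups:

* **genotype I/O** — HapMap-dialect and plain genotype-TSV tables with a
  canonical allele-dosage encoding;
* **QC** — per-locus missing rate, heterozygosity and MAF, with the two
  standard filtering tiers (primary: missing ≤ 20 %, het ≤ 20 %,
  MAF ≥ 5 %; stringent structure subset: missing < 5 %, GD > 0.45);
* **diversity** — gene diversity `GD = 1 − Σᵤ p̃ᵤ²` (optionally
  corrected by `1 − (1+f)/n` for inbreeding `f` and sample size `n`) and
  polymorphism information content
  `PIC = 1 − Σᵤ p̃ᵤ² − Σᵤ<ᵥ 2 p̃ᵤ² p̃ᵥ²`, group summaries, 10-Mb binned
  genome scans (bins with too few SNPs dropped) and diversity-hotspot
  calling (GD < 0.25 low / > 0.40 high);
* **divergence** — between-group allele-frequency comparison: private
  (“unique”) SNP screening, Pearson χ² on 2×2 allele-count tables at
  α = 0.001, ranking by |Δp|, and per-bin variant-SNP ratios;
* **LD** — composite `r²` (squared Pearson correlation of dosages) for
  intrachromosomal pairs, distance-interval profiles, and the decay
  distance as the first interval with mean `r²` < 0.1;
* **relatedness** — identity-by-state similarity ratios (whole-genome and
  per 10-Mb bin), conserved-segment detection (subset mean > 0.85), and
  the VanRaden kinship matrix `K = ZZ′ / 2Σ p(1−p)`;
* **phylo** — Nei (1972) standard genetic distance (Nei 1983 D_A as an
  alternative) between lines and Saitou–Nei neighbor joining with Newick
  output;
* **structure_post** — Evanno ΔK from admixture-model log-likelihood
  replicates and threshold-based group assignment with a “Mixed” class;
* **simulate** — a seeded generator of structured inbred panels
  (Balding–Nichols group divergence, distance-decaying haplotype
  correlation, admixed lines, forced divergent windows, founder-derived
  conserved segments) with a truth manifest, so every scan has a
  recoverable ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a seeded
synthetic panel (300 inbred lines: 150 temperate-like, 130 tropical-like,
20 admixed; ~4,800 array-style SNPs on ten 150-Mb chromosomes) with one
planted allele-frequency gap in the 130-Mb bin of chromosome 2 and one
founder-derived segment spanning 30–120 Mb of chromosome 7:

```bash
cd analysis
python 01_simulate_panel.py
python 04_divergence_scan.py
python 05_ld_decay.py
python 06_similarity_kinship.py
```

prints (abridged):

```
panel (seed 2016): 300 lines x 4817 SNPs -> scratch/panel
highest variant ratio: chr 2 @ 130 Mb with 26/26 = 1.0000
genome-wide LD decay interval (mean r2 < 0.1):
  entire     0.5-0.75 Mb (649330 pairs)
  Temperate  1-1.5 Mb (649316 pairs)
  Tropical   0.25-0.5 Mb (648608 pairs)
mean similarity ratio 0.606; max 0.759 (Tropical_000, Tropical_007); ...
2 conserved region(s) with subset mean > 0.85:
  chr 2 130-140 Mb, 26 SNPs, mean 0.871
  chr 7 30-120 Mb, 283 SNPs, mean 0.978
kinship: 55.0% of pairs at zero after clipping; 99.9% between 0 and 0.5
```

Reading the numbers: the planted divergent window is recovered as the
bin with the top variant-SNP ratio (every one of its 26 tested SNPs
diverges significantly at α = 0.001); the tropical-like group, simulated
with a 5× shorter haplotype-correlation length, decays below `r² = 0.1`
within 0.25–0.5 Mb while the temperate-like group holds LD to 1–1.5 Mb
and the pooled panel sits in between; and the planted founder segment is
recovered exactly as the 30–120 Mb run of chromosome-7 bins whose mean
similarity to the founder (over its 30 most-similar lines) exceeds 0.85.
Each driver writes its tables under `results/`.

The same operations are available as a CLI, e.g.

```bash
panelscan simulate --preset paper --seed 1 --out-dir scratch/demo
panelscan qc --genotypes scratch/demo/panel.tsv --out-summary qc.tsv
panelscan tree --genotypes scratch/demo/panel.tsv --out tree.nwk
```

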