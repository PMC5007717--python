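"""Pairwise identity-by-state similarity, the founder-focused conserved
segment scan, and the VanRaden kinship distribution.

The focal line is the planted tropical founder; its 30 most-similar lines
form the comparison subset, and contiguous 10-Mb bins with subset mean
similarity > 0.85 are reported as conserved regions.
"""

from _common import PANEL_BINSPEC, get_panel, save

from panelscan import relatedness as rel


def main():
    b = get_panel()
    sim, report = rel.similarity_matrix(b.genotypes)
    print(f"mean similarity ratio {report['mean']:.3f}; "
          f"max {report['max_pair'][2]:.3f} ({report['max_pair'][0]}, "
          f"{report['max_pair'][1]}); min {report['min_pair'][2]:.3f} "
          f"({report['min_pair'][0]}, {report['min_pair'][1]})")

    focal = b.manifest.segments[0]["founder"]
    top = rel.most_similar_lines(sim, focal, k=30)
    save(top.round(4), "similarity_top30.tsv")

    binned = rel.binned_similarity(b.genotypes, b.snp_map, focal,
                                   top.line_id.tolist(), PANEL_BINSPEC)
    save(binned.per_bin.round(4), "similarity_bins.tsv")
    save(binned.per_chromosome.round(4), "similarity_chromosomes.tsv")

    regions = rel.conserved_regions(binned.per_bin, threshold=0.85)
    save(regions.round(4), "conserved_regions.tsv")
    print(f"{len(regions)} conserved region(s) with subset mean > 0.85:")
    for _, r in regions.iterrows():
        print(f"  chr {r.chromosome} {r.bin_start_bp // 10**6}-"
              f"{r.bin_end_bp // 10**6} Mb, {r.n_snps} SNPs, "
              f"mean {r.mean_similarity:.3f}")

    kin = rel.vanraden_kinship(b.genotypes)
    dist = rel.kinship_distribution(kin)
    save(dist["histogram"].round(5), "kinship_histogram.tsv")
    below_half = dist["histogram"].query("upper <= 0.5")["fraction"].sum()
    print(f"kinship: {dist['fraction_zero']:.1%} of pairs at zero after "
          f"clipping; {below_half:.1%} between 0 and 0.5")


if __name__ == "__main__":
    main()
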