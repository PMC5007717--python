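"""Per-SNP QC summaries and the two filtering tiers.

Reports how many SNPs survive the primary filter (missing rate <= 20%,
heterozygosity <= 20%, MAF >= 5%) and the stringent structure-analysis
subset (missing rate < 5%, gene diversity > 0.45).
"""

from _common import SCRATCH, get_panel, save

import pandas as pd

from panelscan import qc


def main():
    b = get_panel()
    summaries = qc.locus_summaries(b.genotypes, b.snp_map)
    primary = qc.filter_primary(summaries)
    structure = qc.filter_structure_subset(summaries)
    summaries["kept_primary"] = summaries.index.isin(primary)
    summaries["kept_structure"] = summaries.index.isin(structure)
    SCRATCH.mkdir(exist_ok=True)
    summaries.round(6).to_csv(SCRATCH / "qc_per_snp.tsv", sep="\t", index=False,
                              lineterminator="\n")
    print(f"  wrote scratch/qc_per_snp.tsv ({len(summaries)} rows)")
    print(f"{len(summaries)} SNPs genotyped; {len(primary)} pass the primary "
          f"filter; {len(structure)} form the stringent subset")
    overview = pd.DataFrame([{
        "n_snps": len(summaries),
        "n_primary": len(primary),
        "n_structure_subset": len(structure),
        "mean_maf": summaries.maf.mean(),
        "mean_het": summaries.het_rate.mean(),
        "mean_missing": summaries.missing_rate.mean(),
    }])
    save(overview, "qc_overview.tsv")


if __name__ == "__main__":
    main()
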