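"""LD decay: mean r2 per distance interval and the decay-distance table
(r2 < 0.1 rule) for the entire panel and each group, per chromosome and
genome-wide.
"""

from _common import get_panel, save

import pandas as pd

from panelscan import ld as ldm


def main():
    b = get_panel()
    table = ldm.decay_by_panel_and_chromosome(b.genotypes, b.snp_map, b.groups)
    mb = 1_000_000
    table["decay_interval_mb"] = [
        "beyond grid" if pd.isna(lo) else f"{lo / mb:g}-{hi / mb:g}"
        for lo, hi in zip(table.decay_lower_bp, table.decay_upper_bp)
    ]
    save(table, "ld_decay.tsv")
    print("genome-wide LD decay interval (mean r2 < 0.1):")
    for _, r in table[table.chromosome == "total"].iterrows():
        print(f"  {r.panel:<10} {r.decay_interval_mb} Mb ({r.n_pairs} pairs)")

    # full profile for the entire panel, pooled over chromosomes
    pooled = []
    chroms = sorted(set(b.snp_map.chromosome), key=lambda c: int(c))
    for chrom in chroms:
        pooled.append(ldm.pairwise_r2(b.genotypes, b.snp_map, chrom))
    prof = ldm.decay_profile(pd.concat(pooled, ignore_index=True))
    save(prof.table.round(5), "ld_profile_entire.tsv")


if __name__ == "__main__":
    main()
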