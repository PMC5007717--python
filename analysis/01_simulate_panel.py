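"""Generate the emulated structured panel and write it to scratch/.

The panel mirrors the structure of a temperate/tropical maize breeding
collection at reduced scale: 150 temperate-like + 130 tropical-like +
20 admixed inbred lines, ~5,000 array-style SNPs (MAF >= 0.05) on 10
chromosomes of 150 Mb, one forced allele-frequency gap in the 130-Mb bin
of chromosome 2, and 30 lines derived from a tropical founder sharing the
30-120 Mb segment of chromosome 7.
"""

from _common import SCRATCH, SEED, get_panel, save

import pandas as pd

from panelscan import io as pio


def main():
    bundle = get_panel()
    out = SCRATCH / "panel"
    out.mkdir(parents=True, exist_ok=True)
    pio.write_genotype_table(bundle.snp_map, bundle.genotypes, out / "panel.tsv")
    pio.write_group_assignment(bundle.groups, out / "groups.tsv")
    bundle.manifest.to_json(out / "truth.json")
    print(f"panel (seed {SEED}): {bundle.genotypes.n_lines} lines x "
          f"{bundle.genotypes.n_snps} SNPs -> {out}")
    summary = pd.DataFrame([
        {"group": label, "n_lines": int((bundle.groups == label).sum())}
        for label in bundle.groups.unique()
    ])
    summary["n_snps"] = bundle.genotypes.n_snps
    save(summary, "panel_summary.tsv")


if __name__ == "__main__":
    main()
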