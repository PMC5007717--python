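"""Shared settings for the analysis drivers.

All drivers analyse the same seeded, reduced-scale emulated panel: two
groups (temperate-like and tropical-like) plus admixed lines, one planted
divergent window and one planted founder-derived conserved segment.  At
this SNP density (~33 expected SNPs per 10-Mb bin instead of the ~208 of
a full-density array) the bin drop rule is scaled proportionally to a
minimum of 5 SNPs per bin.
"""

from pathlib import Path

from panelscan._bins import BinSpec
from panelscan.simulate import emulate_paper_panel

SEED = 2016

#: drop rule scaled to the reduced SNP density of the emulated panel
PANEL_BINSPEC = BinSpec(bin_size_bp=10_000_000, min_snps_per_bin=5)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_panel():
    RESULTS.mkdir(exist_ok=True)
    return emulate_paper_panel(SEED)


def save(df, name, **kw):
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.6g", **kw)
    print(f"  wrote {path.relative_to(ROOT)}")
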