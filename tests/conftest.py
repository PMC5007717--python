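import numpy as np
import pandas as pd
import pytest

from panelscan.io import GenotypeMatrix, SnpMap
from panelscan.simulate import emulate_paper_panel

#: fixed seed for the emulated study panel used across tests
PANEL_SEED = 2016


def make_map(n, chrom="1", start=1, step=1000):
    """A simple placed SNP map with n evenly spaced A/G SNPs."""
    return SnpMap(pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chromosome": chrom,
        "position_bp": np.arange(start, start + n * step, step)[:n],
        "allele_a": "A",
        "allele_b": "G",
    }))


def make_matrix(calls, line_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    if line_ids is None:
        line_ids = [f"L{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(line_ids, calls)


@pytest.fixture(scope="session")
def emulated_panel():
    """The reduced-scale study-mirroring panel, shared across tests."""
    return emulate_paper_panel(PANEL_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
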