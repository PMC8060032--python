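import numpy as np
import pandas as pd
import pytest

import pharmagenic as pg
from pharmagenic.simulate import make_gene_annotations


@pytest.fixture(scope="session")
def small_panel():
    """Six AR(1) blocks of 25 SNPs, moderate LD, with variant metadata."""
    return pg.make_ld_panel(n_blocks=6, block_size=25, ar1_rho=0.6, seed=3)


@pytest.fixture(scope="session")
def ldsc_panel():
    """Genome-like panel: 400 blocks x 50 SNPs, heterogeneous LD strength."""
    return pg.make_ld_panel(n_blocks=400, block_size=50, ar1_rho=(0.0, 0.9), seed=1)


@pytest.fixture(scope="session")
def ldsc_scores(ldsc_panel):
    return pg.compute_ld_scores(ldsc_panel)


@pytest.fixture(scope="session")
def small_annotations(small_panel):
    return make_gene_annotations(small_panel, snps_per_gene=5)


@pytest.fixture()
def toy_sumstats():
    """Five variants with hand-set fields for filter arithmetic."""
    df = pd.DataFrame({
        "snp": ["v1", "v2", "v3", "v4", "v5"],
        "chrom": ["1", "1", "6", "2", "2"],
        "pos": [1000, 2000, 30_000_000, 5000, 6000],
        "a1": ["A", "C", "G", "T", "A"],
        "a2": ["G", "T", "A", "C", "C"],
        "maf": [0.3, 0.005, 0.2, 0.4, 0.1],
        "beta": [0.2, 0.1, -0.3, 0.05, 0.0],
        "se": [0.1, 0.1, 0.1, 0.1, 0.1],
        "p": [0.045, 0.3, 0.002, 0.6, 0.99],
        "n": [10_000] * 5,
    })
    return pg.SumStats(df)
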