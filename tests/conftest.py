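import numpy as np
import pandas as pd
import pytest

from asepop import simdata


SMALL_SIM = simdata.SimConfig(
    n_families=24,
    n_genes=200,
    n_dase_genes=20,
    library_size_mean=200_000,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared across read-only tests."""
    return simdata.simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def small_meta(small_cohort):
    return small_cohort.metadata


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def snp_frame():
    """Hand-built SNP count table covering all filter boundaries."""
    rows = [
        # ref, alt
        (5, 5),    # keep: total 10, ratio 0
        (0, 50),   # drop: monoallelic
        (2, 8),    # drop: |log2(8/2)| = 2 not < 2
        (4, 6),    # keep
        (2, 9),    # drop: |log2(9/2)| ~ 2.17 >= 2
        (1, 8),    # drop: total 9 < 10
    ]
    return pd.DataFrame(
        {
            "sample": "s1",
            "contig": "chr1",
            "position": np.arange(100, 100 + len(rows)),
            "variantID": [f"v{i}" for i in range(len(rows))],
            "refAllele": "A",
            "altAllele": "G",
            "refCount": [r for r, _ in rows],
            "altCount": [a for _, a in rows],
            "totalCount": [r + a for r, a in rows],
        }
    )
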