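import numpy as np
import pandas as pd
import pytest

from mkm import (CountTable, SampleMetadata, SimParams, simulate_community,
                 simulate_genotypes)


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale simulated study: 30 accessions x 3 reps, both organs."""
    params = SimParams(
        n_accessions=30, n_replicates=3, n_snps=300,
        n_taxa_bacteria=25, n_taxa_fungi=25, seed=11,
    )
    geno = simulate_genotypes(params)
    return simulate_community(geno, params)


@pytest.fixture()
def toy_table():
    """3 samples x 4 taxa, hand-checkable."""
    counts = pd.DataFrame(
        [[5, 0, 2, 3], [1, 4, 0, 0], [0, 2, 2, 1]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    kingdom = pd.Series("bacteria", index=counts.columns, dtype=object)
    lineage = pd.Series(
        ["k__Bacteria;p__A;c__X;o__;f__;g__G1",
         "k__Bacteria;p__A;c__X;o__;f__;g__G1",
         "k__Bacteria;p__B;c__Y;o__;f__;g__G2",
         "k__Bacteria;p__B;c__Y;o__;f__;g__G3"],
        index=counts.columns, dtype=object,
    )
    return CountTable(counts, kingdom, lineage)


@pytest.fixture()
def two_sample_meta():
    """One leaf and one root sample, equal depth — the balanced design of
    the per-genus worked examples."""
    def make(total: int = 1000) -> SampleMetadata:
        return SampleMetadata(pd.DataFrame({
            "sample_id": ["L1", "R1"],
            "accession_id": ["acc1", "acc1"],
            "organ": ["leaf", "root"],
            "block": ["b1", "b1"],
            "run": ["r1", "r1"],
            "total_reads": [total, total],
        }))
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
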