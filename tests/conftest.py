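import numpy as np
import pandas as pd
import pytest

from clonefate.types import CloneTree, SegmentProfile

MB = 1_000_000


def make_profile(sample_id, rows, genome, ploidy=2.0):
    """rows: (chrom, start_mb, end_mb, cn_a, cn_b, n_het_snps)"""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cn_a", "cn_b", "n_het_snps"]
    )
    df["start"] *= MB
    df["end"] *= MB
    return SegmentProfile(sample_id, df, ploidy, {c: l * MB for c, l in genome.items()})


@pytest.fixture
def chain_tree():
    return CloneTree("T1", {"B": "A", "C": "B"})


@pytest.fixture
def branch_tree():
    return CloneTree("T1", {"B": "A", "C": "A"})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
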