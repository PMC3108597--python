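import numpy as np
import pytest

from mthap.hapio import AlignedDataset, SampleRecord, collapse_haplotypes


def make_dataset(seqs, pops=None, groups=None, ids=None):
    """Build an AlignedDataset from parallel lists."""
    n = len(seqs)
    pops = pops or ["P1"] * n
    groups = groups or ["-"] * n
    ids = ids or [f"s{i+1}" for i in range(n)]
    return AlignedDataset(
        [SampleRecord(i, p, g, s) for i, p, g, s in zip(ids, pops, groups, seqs)]
    )


def random_dataset(rng, n=10, L=12, n_pops=2, n_groups=1, alphabet="ACGT"):
    """Random (not necessarily realistic) aligned dataset for property tests."""
    seqs = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
    pops = [f"P{rng.integers(1, n_pops + 1)}" for _ in range(n)]
    groups = [f"g{rng.integers(1, n_groups + 1)}" for _ in range(n)]
    return make_dataset(seqs, pops, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def two_pop_fixed():
    """Two populations each fixed for a different haplotype (2+2)."""
    return make_dataset(
        ["AAAA", "AAAA", "GGGG", "GGGG"],
        pops=["P1", "P1", "P2", "P2"],
    )


@pytest.fixture
def two_pop_fixed_table(two_pop_fixed):
    return collapse_haplotypes(two_pop_fixed)
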