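import numpy as np
import pytest

from flukeprint.hapcall import ReferenceDB
from flukeprint.synthdata import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast cohort: few haplotypes, few samples, modest depth."""
    return SimConfig(
        seed=42,
        n_haplotypes=10,
        n_samples=4,
        reads_per_sample=1500,
        n_positive_controls=2,
        n_negative_controls=1,
        n_circulating_haplotypes=4,
    )


@pytest.fixture
def tiny_db(rng):
    """Five random, well-separated 379 bp reference haplotypes."""
    seqs = {}
    while len(seqs) < 5:
        s = "".join(rng.choice(list("ACGT"), 379))
        seqs[f"CR{len(seqs) + 1:02d}"] = s
    return ReferenceDB(seqs)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), length))
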