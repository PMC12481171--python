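import numpy as np
import pytest

from bulkmap.config import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A compact two-chromosome study: one planted QTL, one empty chromosome."""
    return SimConfig(
        seed=7,
        chrom_lengths={"A09": 3_000_000, "A06": 3_000_000},
        n_snps=600,
        n_indels=240,
        qtls=[("A09", 1_500_000, -1.15)],
        n_genes=200,
        n_de_genes=30,
    )
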