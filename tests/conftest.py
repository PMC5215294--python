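import numpy as np
import pytest

from poisedchrom.io_formats import Tag
from poisedchrom.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """A scaled-down simulation: 30 genes on short chromosomes, light
    background — fast enough for smoke tests of the full chain."""
    return SimConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=700_000,
        n_genes=30,
        background_rate=0.02,
    )


def random_tags(rng, n, chrom="chr1", chrom_length=10_000, read_length=36):
    """Uniform random tags on one chromosome, sorted by start."""
    starts = np.sort(rng.integers(0, chrom_length - read_length, n))
    strands = rng.random(n) < 0.5
    return [
        Tag(chrom, int(s), int(s) + read_length, "+" if p else "-")
        for s, p in zip(starts, strands)
    ]
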