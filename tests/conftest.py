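import numpy as np
import pytest

from tfkinetics.intervals import GenomicInterval
from tfkinetics.synthetic import NoiseModel, generate_genome


@pytest.fixture(scope="session")
def genome():
    """Default toy genome: 1 chrom x 2 Mb, 200 genes, 500 sites, uniform classes."""
    return generate_genome(seed=7)


@pytest.fixture(scope="session")
def clean_noise():
    return NoiseModel(peak_dropout_prob=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chrom="chr1", max_pos=100_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(GenomicInterval(chrom, start, start + int(rng.integers(1, max_len))))
    return out


@pytest.fixture()
def make_random_intervals(rng):
    return lambda n, **kw: random_intervals(rng, n, **kw)
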