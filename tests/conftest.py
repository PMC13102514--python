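import numpy as np
import pytest

from t2tpop.core_io import Interval
from t2tpop.synthetic_data import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact study configuration shared by genome-level tests."""
    return SimConfig(
        seed=42,
        chromosome_lengths={"chr1": 120_000, "chr2": 90_000},
        satellite_copies=40,
        inversion=Interval("chr1", 15_000, 55_000),
        snp_count=1_500,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)


def random_intervals(rng, n, chroms=("c1", "c2"), max_pos=10_000, max_len=500):
    """Random interval sets for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, start + length))
    return out


def bitmap_cover(intervals, chroms, size):
    """Per-base boolean coverage bitmap — the oracle for interval algebra."""
    maps = {c: np.zeros(size, dtype=bool) for c in chroms}
    for iv in intervals:
        maps[iv.chrom][iv.start : iv.end] = True
    return maps
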