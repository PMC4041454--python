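import numpy as np
import pytest

from cistra.enrichment import GenomeSpec
from cistra.intervals import GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def one_chrom_genome():
    return GenomeSpec({"chr1": 10_000_000})


@pytest.fixture
def two_chrom_genome():
    return GenomeSpec({"chr1": 10_000_000, "chr2": 8_000_000})


def random_peakset(rng, n, chrom_len=10_000_000, max_len=1000, name="rand",
                   chroms=("chr1",)):
    intervals = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_len - length + 1))
        intervals.append(GenomicInterval(chrom, start, start + length))
    return PeakSet(name, intervals)


@pytest.fixture
def make_peakset():
    def _make(spec_list, name="ps"):
        return PeakSet(
            name, [GenomicInterval(c, s, e) for c, s, e in spec_list]
        )

    return _make
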