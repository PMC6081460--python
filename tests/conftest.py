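import numpy as np
import pytest

from oncomark.coverage import CoverageTrack, ReadInterval, bin_genome


@pytest.fixture
def small_grid():
    return bin_genome({"chr1": 1000, "chr2": 600}, 200)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_track(grid, values, sample_id="s", state="per_million", total_reads=1_000_000):
    return CoverageTrack(
        grid=grid,
        sample_id=sample_id,
        values=np.asarray(values, dtype=float),
        total_reads=total_reads,
        normalization_state=state,
    )


def random_reads(rng, chrom_sizes, n, read_length=50, extra_chrom_frac=0.0):
    """Random reads, optionally with a fraction on an off-grid chromosome."""
    chroms = list(chrom_sizes)
    reads = []
    for _ in range(n):
        if extra_chrom_frac and rng.random() < extra_chrom_frac:
            chrom, size = "chrUn", 10_000
        else:
            chrom = chroms[rng.integers(len(chroms))]
            size = chrom_sizes[chrom]
        start = int(rng.integers(0, max(1, size - read_length)))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(ReadInterval(chrom, start, start + read_length, strand))
    return reads
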