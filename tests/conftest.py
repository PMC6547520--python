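import numpy as np
import pytest

from chromloop import GenomeDef, Interval, PeakSet, SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_genome() -> GenomeDef:
    return GenomeDef({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def default_bundle():
    """One shared default-condition synthetic bundle (seed 0)."""
    return simulate_all(SimConfig(seed=0))


def random_peakset(rng: np.random.Generator, genome: GenomeDef, n: int,
                   max_len: int = 500, label: str = "rand") -> PeakSet:
    ivs = []
    names = genome.chrom_names
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - length))
        ivs.append(Interval(chrom, start, start + length))
    return PeakSet(ivs, label=label)
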