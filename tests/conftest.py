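import numpy as np
import pytest

from chromintegrate.intervals import GenomicInterval, PeakSet
from chromintegrate.simulate import SimulationConfig, generate_annotation, generate_truth


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast single-chromosome study used across unit tests."""
    return SimulationConfig(
        seed=7, n_chroms=1, chrom_length=1_000_000, n_genes=100, depth=20_000
    )


@pytest.fixture(scope="session")
def small_ann(small_cfg):
    return generate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_ann):
    return generate_truth(small_cfg, small_ann)


def random_peakset(rng: np.random.Generator, n: int, chrom_len: int = 10_000,
                   chrom: str = "chrT", max_width: int = 500) -> PeakSet:
    """n random intervals on a toy chromosome (may mutually overlap)."""
    starts = rng.integers(0, chrom_len - max_width, n)
    widths = rng.integers(1, max_width, n)
    return PeakSet(
        [GenomicInterval(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)]
    )


def base_mask(peaks: PeakSet, chrom: str, chrom_len: int) -> np.ndarray:
    """Per-base boolean occupancy oracle on a toy chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in peaks:
        if iv.chrom == chrom:
            mask[iv.start: iv.end] = True
    return mask
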