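import numpy as np
import pytest

from multicistrome.intervals import GenomicInterval, IntervalSet
from multicistrome.pipeline import PipelineRun, config_for_synthetic
from multicistrome.synthetic import SimulationConfig, simulate_dataset


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_pos: int = 1000,
    max_len: int = 50,
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        end = start + int(rng.integers(1, max_len + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs)


def brute_force_overlap(a: IntervalSet, b: IntervalSet, min_bp: int = 1):
    """All-pairs reference implementation for overlap queries."""
    pairs = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if (
                x.chrom == y.chrom
                and min(x.end, y.end) - max(x.start, y.start) >= min_bp
            ):
                pairs.append((i, j))
    return pairs


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A down-scaled study for fast structural tests."""
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=150_000,
        n_genes=40,
        n_core_peaks=30,
        n_specific_per_sample=8,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    return simulate_dataset(small_config, tmp_path_factory.mktemp("small_data"))


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default-sized synthetic study used by the recovery suite."""
    return simulate_dataset(
        SimulationConfig(seed=1), tmp_path_factory.mktemp("default_data")
    )


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run over the default synthetic study."""
    run = PipelineRun(
        config_for_synthetic(default_dataset), tmp_path_factory.mktemp("default_out")
    )
    run.run()
    return run
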