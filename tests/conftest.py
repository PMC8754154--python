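import numpy as np
import pytest

from ttkinetics.intervals import Gene, GenomeAnnotation, GenomicInterval
from ttkinetics.simulate import SimulationConfig, simulate_tracks


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment shared across tests (seed 1)."""
    return simulate_tracks(SimulationConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_gene_annotation():
    """A plus- and a minus-strand gene on one toy chromosome."""
    g1 = Gene(
        "gA",
        GenomicInterval("chr1", 10_000, 20_000, "+"),
        [
            GenomicInterval("chr1", 10_000, 12_000, "+"),
            GenomicInterval("chr1", 18_000, 20_000, "+"),
        ],
    )
    g2 = Gene(
        "gB",
        GenomicInterval("chr1", 60_000, 72_000, "-"),
        [
            GenomicInterval("chr1", 60_000, 62_000, "-"),
            GenomicInterval("chr1", 70_000, 72_000, "-"),
        ],
    )
    return GenomeAnnotation([g1, g2], {"chr1": 100_000})
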