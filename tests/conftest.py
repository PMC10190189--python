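import numpy as np
import pytest

from gbsmedip import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """60 kb single-chromosome genome with islands and planted PstI sites."""
    return sim.simulate_genome(
        n_chrom=1,
        chrom_length_bp=60_000,
        gc_fraction=0.42,
        island_density=0.02,
        seed=7,
        site_spacing_bp=(150, 900),
    )


@pytest.fixture(scope="session")
def small_fragments(small_genome):
    return sim.digest_genome(small_genome)


@pytest.fixture(scope="session")
def study_genome():
    """Multi-chromosome genome at the scale the calibration runs use."""
    return sim.simulate_genome(
        n_chrom=3,
        chrom_length_bp=1_200_000,
        gc_fraction=0.42,
        island_density=0.02,
        seed=11,
        site_spacing_bp=(150, 900),
    )


@pytest.fixture(scope="session")
def study_fragments(study_genome):
    return sim.digest_genome(study_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
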