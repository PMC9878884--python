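import numpy as np
import pytest

from linpan import build_pangenome
from linpan.simulate import SimulationConfig, simulate_pangenome_inputs


@pytest.fixture(scope="session")
def small_sim():
    """3 derived genomes, 10 insertions each (51-5000 bp), 10 accessions."""
    cfg = SimulationConfig(
        seed=11,
        chrom_length=200_000,
        n_genomes=3,
        insertions_per_genome=10,
        insertion_len_range=(51, 5_000),
        n_accessions=10,
        coverage_depth=10.0,
    )
    return simulate_pangenome_inputs(cfg)


@pytest.fixture(scope="session")
def small_pangenome(small_sim):
    founder, derived, _manifest = small_sim
    return build_pangenome(founder, derived)


@pytest.fixture(scope="session")
def cassette_sim():
    """Small sim with one duplicated >1 kb cassette (translocation bait)."""
    cfg = SimulationConfig(
        seed=5,
        chrom_length=100_000,
        n_genomes=2,
        insertions_per_genome=3,
        insertion_len_range=(60, 1_000),
        n_cassette_pairs=1,
        cassette_length=1_200,
        n_accessions=6,
    )
    return simulate_pangenome_inputs(cfg)


@pytest.fixture(scope="session")
def cassette_pangenome(cassette_sim):
    founder, derived, _manifest = cassette_sim
    return build_pangenome(founder, derived)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
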