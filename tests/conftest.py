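import numpy as np
import pytest

from circdigit import (
    build_kmer_index,
    build_toy_genome,
    simulate_expression_truth,
    simulate_read_set,
)


@pytest.fixture(scope="session")
def genome3():
    """Three-gene toy genome used across modules."""
    return build_toy_genome(11, n_genes=3)


@pytest.fixture(scope="session")
def index3(genome3):
    return build_kmer_index(genome3, 20)


@pytest.fixture(scope="session")
def truth3(genome3):
    return simulate_expression_truth(genome3, 7, circ_fraction=1.0)


@pytest.fixture(scope="session")
def single_circle_world():
    """One 3-exon gene whose middle exon circularizes; reads with
    min_overhang equal to the anchor length so truth labels coincide with
    what an anchor-based caller can use."""
    genome = build_toy_genome(
        21, n_genes=1, exons_per_gene=(3, 3), exon_len=(100, 100), intron_len=(60, 80)
    )
    truth = simulate_expression_truth(genome, 22, circ_fraction=1.0)
    reads = simulate_read_set(
        genome, truth, n_fragments=4000, read_len=60, seed=23, min_overhang=20
    )
    return genome, truth, reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
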