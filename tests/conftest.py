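import numpy as np
import pytest

from ervscan.discovery import LtrReference, detect_insertions
from ervscan.simulate import SimulationConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def tiny_config():
    """A small cohort that exercises every feature in seconds."""
    return SimulationConfig(
        seed=11,
        chromosomes={"chr1": 300_000, "chr2": 200_000},
        n_insertions=6,
        n_reference_ervs=2,
        n_individuals=8,
        n_snps=400,
        depth=10.0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_all(tiny_config)


@pytest.fixture(scope="session")
def tiny_detection(tiny_dataset):
    ds = tiny_dataset
    return detect_insertions(
        ds.read_batches(), ds.reference, LtrReference("LTR", ds.ltr),
        reference_erv_intervals=ds.ref_erv_bed,
        known_nonref_sites=ds.known_nonref_bed,
        sv_deletions=ds.sv_deletions,
        groups=ds.truth.populations,
    )


@pytest.fixture(scope="session")
def genotype_cohort():
    """A read-free cohort at association scale (n = 500, common insertions)."""
    cfg = SimulationConfig(
        seed=7,
        chromosomes={"chr1": 2_000_000, "chr2": 1_500_000, "chr3": 1_500_000},
        n_insertions=12,
        insertion_freq_min=0.2,
        insertion_freq_max=0.8,
        n_individuals=500,
        n_populations=2,
        n_snps=2_000,
    )
    from ervscan.simulate import simulate_haplotypes

    genotypes, truth = simulate_haplotypes(cfg)
    return cfg, genotypes, truth
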