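import numpy as np
import pytest
from hypothesis import settings

from esoxsynt.simdata import SimConfig, apply_wgd, simulate_ancestral_genome

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def wgd_genome():
    """Small post-WGD genome shared by homology/profile tests: 4 chromosomes
    x 6 genes duplicated at 18% divergence."""
    cfg = SimConfig(seed=11, n_chromosomes_ancestral=4, genes_per_chromosome=6)
    genome, truth = simulate_ancestral_genome(cfg)
    rng = np.random.default_rng(12)
    return apply_wgd(genome, truth, 0.18, rng, label="3R")


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
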