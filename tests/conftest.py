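import numpy as np
import pytest

from cyanophen import pipeline, syndata


@pytest.fixture(scope="session")
def small_population():
    """One desk-scale half-sib trial shared across tests: 49 families x 6,
    block LD genotypes, 201-band spectra, HCN-like trait (35% additive,
    20% spectral)."""
    ped = syndata.simulate_pedigree(49, 6, 30, 4, seed=11)
    geno = syndata.simulate_genotypes(ped, seed=12)
    spec = syndata.simulate_spectra(ped, seed=13)
    trait, params = syndata.simulate_trait(ped, geno, spec, h2_additive=0.35,
                                           spectral_share=0.2, seed=14)
    return ped, geno, spec, trait, params


@pytest.fixture(scope="session")
def analysis_data(small_population):
    ped, geno, spec, trait, _ = small_population
    return pipeline.prepare_data(ped, geno, spec, trait)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_26)
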