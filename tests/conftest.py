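import numpy as np
import pytest

import bagwas as bw


@pytest.fixture(scope="session")
def small_config():
    return bw.SimConfig(n_individuals=1500, n_variants=120, ld_block_size=12,
                        block_rho=0.6, n_causal=6, h2_bag=0.25, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return bw.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_panel):
    cohort, arch = bw.simulate_cohort(small_panel, small_config)
    return small_panel, cohort, arch


@pytest.fixture(scope="session")
def small_fixture(small_config, small_study):
    panel, cohort, arch = small_study
    return bw.simulate_omics_fixtures(panel, arch, small_config)


@pytest.fixture(scope="session")
def small_gwas(small_study):
    panel, cohort, arch = small_study
    return bw.gwas_linear(panel, cohort.bag_true, cohort.covariates())
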