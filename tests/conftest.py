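import numpy as np
import pytest

from halfsib import mcmc, synthetic

# Table-style posterior-mean covariance matrices, canonical order
# (W100S, SOC, PEC); also the synthetic generator's defaults.
G0_REF = synthetic.DEFAULT_G0
R0_REF = synthetic.DEFAULT_R0


@pytest.fixture(scope="session")
def ref_matrices():
    return G0_REF.copy(), R0_REF.copy()


@pytest.fixture(scope="session")
def small_sim():
    """A reduced study-condition trial: 60 families, 2 blocks, reference
    dispersion truths."""
    cfg = synthetic.default_config(n_families=60, seed=42)
    table, true_g = synthetic.simulate_phenotypes(cfg)
    return cfg, table, true_g


@pytest.fixture(scope="session")
def short_samples(small_sim):
    """A short but usable chain on the reduced trial (shared across test
    modules to keep the suite fast)."""
    _, table, _ = small_sim
    cfg = mcmc.McmcConfig(n_iter=3000, burn_in=1000, thin=5, seed=7)
    return mcmc.fit_gibbs(table, mcmc.ModelSpec(), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
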