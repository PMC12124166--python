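import numpy as np
import pytest

import camsom


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated survey at the default study design (20 stations, 29
    species, 49 days in 5-day occasions), shared across tests."""
    return camsom.simulate_dataset(camsom.SimulationScenario(seed=1))


@pytest.fixture(scope="session")
def short_model1_fit(default_dataset):
    """A short Model 1 (abundance-covariate) fit reused by tests that only
    need plausible posterior draws, not a converged chain."""
    cfg = camsom.MCMCConfig(n_chains=2, n_iter=1200, burn_in=600, thin=3, seed=7)
    return camsom.fit_msom(
        default_dataset.history,
        default_dataset.stations,
        camsom.ModelSpec(variant="abundance", n_aug=10),
        cfg,
    )
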