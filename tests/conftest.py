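import numpy as np
import pytest

from dyadsync.simulate import SimulationConfig, simulate_dyad


@pytest.fixture(scope="session")
def coupled_dyad():
    """One reference latent-coupled dyad (child leads by 2 s), La1."""
    cfg = SimulationConfig(coupling_lag_s=-2, seed=11)
    rec, truth = simulate_dyad(cfg, "La1", np.random.SeedSequence(11))
    return rec, truth, cfg


@pytest.fixture(scope="session")
def null_dyad():
    """One uncoupled dyad (independent partners), Rest condition."""
    cfg = SimulationConfig(coupling_gain=0.0, seed=12)
    rec, truth = simulate_dyad(cfg, "Rest", np.random.SeedSequence(12))
    return rec, truth, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
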