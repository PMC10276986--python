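import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """A deterministic miniature quantitative study shared across tests."""
    from wbha import SimulationDesign, simulate_study

    design = SimulationDesign(n=300, m=400, m1=8, rho=0.0, seed=42)
    return simulate_study(design)
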