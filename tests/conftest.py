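import numpy as np
import pytest

from ksrv import SimulationConfig, simulate_paired


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated reference/spatial pair with ground truth."""
    cfg = SimulationConfig(
        n_ref_cells=120,
        n_spots=80,
        n_genes=40,
        n_shared_genes=20,
        seed=42,
    )
    return simulate_paired(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
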