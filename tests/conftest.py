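import warnings

import numpy as np
import pytest

from neutroscope import SimulationConfig, normalize_log, simulate_atlas

warnings.filterwarnings("ignore", message="signature .*dropping")


@pytest.fixture(scope="session")
def small_atlas():
    """Desk-scale synthetic cohort shared across test modules."""
    cfg = SimulationConfig(
        n_samples=6, n_cells_per_sample=300, n_genes=800,
        markers_per_type=10, seed=0,
    )
    adata, samples, truth = simulate_atlas(cfg)
    return cfg, adata, samples, truth


@pytest.fixture(scope="session")
def small_normalized(small_atlas):
    _, adata, _, _ = small_atlas
    return normalize_log(adata)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
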