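import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from amfsoil import CommunityMatrix, SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_counts():
    """Small count matrix with metadata: 2 plots x 2 samples, one date."""
    data = pd.DataFrame(
        [[30, 10, 0, 1],
         [25, 15, 2, 0],
         [2, 5, 40, 0],
         [1, 8, 35, 2]],
        index=["A1", "A2", "B1", "B2"],
        columns=["VT1", "VT2", "VT3", "VT4"])
    meta = pd.DataFrame({
        "plot": ["A", "A", "B", "B"],
        "grid_point": [1, 2, 1, 2],
        "date": pd.to_datetime(["2009-09-03"] * 4),
        "x_m": [0.0, 5.0, 40.0, 45.0],
        "y_m": [0.0, 0.0, 0.0, 0.0],
    }, index=data.index)
    return CommunityMatrix(data, mode="counts", meta=meta)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale study: full design, fewer VT, shallow depths."""
    return SimulationConfig(n_vt=10, depth_range=(13, 120), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One linked synthetic dataset shared across tests (read-only)."""
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def errorfree_dataset():
    """Error-free, decoy-free dataset for exact truth-recovery checks."""
    cfg = SimulationConfig(n_vt=8, depth_range=(13, 60), error_rate=0.0,
                           decoy_hit_fraction=0.0, seed=23)
    return cfg, simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
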