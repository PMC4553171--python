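import numpy as np
import pytest

from swarmcast import (EmbeddingSpec, MGParams, PSOConfig, Topology,
                       build_embedding, fit_scaler, integrate_mg,
                       train_test_split)


@pytest.fixture(scope="session")
def clean_series():
    """The 2000-point noiseless benchmark series (t = 0..1999 s)."""
    return integrate_mg(MGParams(t_horizon=1999.0))


@pytest.fixture(scope="session")
def benchmark_data(clean_series):
    """Embedded 4-tap patterns split 1000 train / 976 validation, with scaler."""
    ds = build_embedding(clean_series, EmbeddingSpec())
    train_set, valid_set = train_test_split(ds, 1000)
    return {"dataset": ds, "train": train_set, "valid": valid_set,
            "scaler": fit_scaler(train_set)}


@pytest.fixture(scope="session")
def quick_pso_config():
    """Short swarm run for unit-level behavior checks."""
    return PSOConfig(n_particles=20, k_max=60, seed=0)
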