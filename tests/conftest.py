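import numpy as np
import pandas as pd
import pytest

from brainagekit.core import FeatureMatrix
from brainagekit.synthetic_data import CohortSpec, SimulationConfig, generate_cohort


def make_feature_matrix(data: pd.DataFrame, measures: dict) -> FeatureMatrix:
    """Wrap an ad-hoc table in a FeatureMatrix with minimal metadata."""
    meta = pd.DataFrame(
        {
            "measure": [measures[c] for c in data.columns],
            "hemisphere": "lh",
            "region": list(data.columns),
        },
        index=pd.Index(data.columns, name="feature"),
    )
    return FeatureMatrix(data=data, meta=meta)


def noise_free_config(**overrides) -> SimulationConfig:
    defaults = dict(
        cohorts={"SIM": CohortSpec(n=60)},
        n_regions=8,
        sigma_delta=0.0,
        apoe_delta_shifts={"e33": 0.0, "e2": 0.0, "e4": 0.0, "e24": 0.0},
        mci_delta_shift=0.0,
        noise_sd={"thickness": 0.0, "volume": 0.0},
        shared_noise_sd={"thickness": 0.0, "volume": 0.0},
        seed=5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-noise two-cohort dataset shared across tests."""
    cfg = SimulationConfig(
        cohorts={"A": CohortSpec(n=150), "B": CohortSpec(n=120, abeta_modality="pet")},
        n_regions=20,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
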