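import numpy as np
import pytest

from causalbind import FitConfig, ModelParameters

MASTER_SEED = 2025


@pytest.fixture
def params() -> ModelParameters:
    """A generic observer: moderate binding, auditory noise >> visual."""
    return ModelParameters(
        p_common=0.3,
        mu_prior=0.5,
        sigma_prior=20.0,
        sigma_v=2.0,
        delta_sigma_v=0.4,
        delta_x_v=0.2,
        sigma_a=7.0,
        delta_x_a=-0.3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture
def quick_fit_config() -> FitConfig:
    """A deliberately small fit budget for structural (non-recovery) tests."""
    return FitConfig(n_sim=500, n_restarts=1, max_evals=60, seed=MASTER_SEED)
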