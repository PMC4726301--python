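import numpy as np
import pytest

from depotsim.fokker_planck import NoiseParams
from depotsim.model_core import ModelParams


@pytest.fixture(scope="session")
def paper_params() -> ModelParams:
    """Reference parameter set: gamma0=20, q=2, c=0.01, d2=1."""
    return ModelParams(gamma0=20.0, q=2.0, c=0.01, d2=1.0)


@pytest.fixture(scope="session")
def reference_noise() -> NoiseParams:
    """Noise set of the effective-potential experiments: M1=0.5, M2=0.05."""
    return NoiseParams(M1=0.5, M2=0.05, mu=0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
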