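import numpy as np
import pytest

from qstox.crypt import CryptConfig, init_crypt
from qstox.hematopoiesis import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def fixed_rate_config() -> CryptConfig:
    """Crypt config with an explicit shed rate: skips the long calibration."""
    return CryptConfig(villus_shed_rate=10.7, villus_init=770.0, seed=42)


@pytest.fixture
def bare_crypt(fixed_rate_config):
    """Un-burned-in crypt state for micro-tests of single mechanisms."""
    cs = init_crypt(fixed_rate_config, burn_in=False)
    # freeze all division clocks so tests control exactly who divides
    cs.clock[:] = 1e9
    return cs


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
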