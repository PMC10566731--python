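import numpy as np
import pytest

from kelpcarb import GeneratorConfig, SeawaterConditions, compute_constants
from kelpcarb.simulate import Exp1Config, Exp2Config


@pytest.fixture(scope="session")
def reference_consts():
    """Constants at the oceanographic reference point S=35, T=25 degC."""
    return compute_constants(SeawaterConditions(25.0, 35.0))


@pytest.fixture(scope="session")
def kelp_habitat():
    """Conditions of the worked kelp-bed example: S=30, T=11 degC."""
    return SeawaterConditions(11.0, 30.0)


@pytest.fixture(scope="session")
def random_states():
    """Seeded random (pH, TA, S, T) states spanning the experimental range."""
    rng = np.random.default_rng(20231011)
    n = 1000
    return np.column_stack([
        rng.uniform(7.0, 8.5, n),     # pH
        rng.uniform(1800, 2500, n),   # TA µmol/kg
        rng.uniform(25, 36, n),       # salinity
        rng.uniform(5, 30, n),        # temperature
    ])


@pytest.fixture()
def noiseless_exp2_cfg():
    return GeneratorConfig(seed=3, exp2=Exp2Config().noiseless())


@pytest.fixture()
def noiseless_exp1_cfg():
    return GeneratorConfig(seed=3, exp1=Exp1Config().noiseless())
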