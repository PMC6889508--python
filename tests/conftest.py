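import numpy as np
import pytest

from relaxkin.global_fit import ArrheniusLaw, GlobalKineticModel
from relaxkin.kinetics_core import MechanismCS, MechanismLK, ObservableModel


@pytest.fixture
def cs_mech():
    """Reference conformational-selection scheme used across the suite."""
    return MechanismCS(k12=2.0, k21=8.0, kon=1.0, koff=5.0)


@pytest.fixture
def lk_mech():
    """Lock-and-key constants of the D194A variant at 288.15 K."""
    return MechanismLK(kon=1.6, koff=7.8)


@pytest.fixture
def obs():
    return ObservableModel()


@pytest.fixture
def lk_model_d194a():
    return GlobalKineticModel(
        kind="lk",
        laws={
            "kon": ArrheniusLaw(k0=1.6, E=8.9),
            "koff": ArrheniusLaw(k0=7.8, E=13.0),
        },
    )


@pytest.fixture
def cs_model():
    return GlobalKineticModel(
        kind="cs",
        laws={
            "k12": ArrheniusLaw(k0=3.0, E=10.0),
            "k21": ArrheniusLaw(k0=12.0, E=12.0),
            "kon": ArrheniusLaw(k0=1.0, E=8.0),
            "koff": ArrheniusLaw(k0=5.0, E=13.0),
        },
    )


@pytest.fixture
def time_grid():
    return np.geomspace(1e-3, 3.0, 300)
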