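import numpy as np
import pytest

from bmameta import StudyData, load_bem_2011
from bmameta.inference import FitSettings


@pytest.fixture(scope="session")
def five_studies():
    return StudyData(y=[0.1, 0.3, -0.05, 0.2, 0.15],
                     se=[0.1, 0.15, 0.2, 0.12, 0.3])


@pytest.fixture(scope="session")
def bem():
    return load_bem_2011()


@pytest.fixture(scope="session")
def light_settings():
    """Cheap MCMC settings for structural unit tests."""
    return FitSettings(chains=2, warmup=500, draws=1000, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
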