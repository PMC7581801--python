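import numpy as np
import pytest

from dbsweep.cohort import AnimalModel, CohortConfig
from dbsweep.waveforms import PulseShape


@pytest.fixture
def cohort_config():
    return CohortConfig(seed=42)


def make_animal(
    I0_true_ua: float = 60.0,
    r_at_2I0: float = 6.0,
    kappa: float = 0.75,
    noise_free: bool = True,
    dyskinesia_prone: bool = False,
) -> AnimalModel:
    """Hand-built animal with controllable parameters (default: noise-free)."""
    return AnimalModel(
        id="rat_test",
        I0_true_ua=I0_true_ua,
        r_at_I0=0.25,
        r_at_2I0=r_at_2I0,
        shape_efficacy={
            PulseShape.RECT: 1.0,
            PulseShape.SINE: kappa,
            PulseShape.TRI: kappa,
            PulseShape.LIN_DEC: kappa,
        },
        dyskinesia_prone=dyskinesia_prone,
        sigma_rate=0.0 if noise_free else 5.0,
        sigma_off=0.0 if noise_free else 1.0,
    )


@pytest.fixture
def nf_animal():
    return make_animal()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
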