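import numpy as np
import pytest

from faaverse.layouts import make_standard_layout
from faaverse.synth import StudyConfig, generate_study


def make_config(**kwargs) -> StudyConfig:
    base = dict(
        study_id="T",
        n_per_group={"diagnosed": 8, "healthy": 8},
        sfreq=125.0,
        duration=20.0,
        seed=0,
    )
    base.update(kwargs)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def layout():
    return make_standard_layout()


@pytest.fixture(scope="session")
def small_raw():
    """One small synthesized study shared by read-only tests."""
    return generate_study(make_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
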