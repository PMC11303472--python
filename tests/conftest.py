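import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from rifpk import DesignSpec, load_preset, simulate_study

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ffm_model():
    return load_preset("ffm")


@pytest.fixture(scope="session")
def base_model():
    return load_preset("base")


@pytest.fixture(scope="session")
def small_study(ffm_model):
    """A small, fast study (6 subjects, 1 occasion worth of times x2) for unit tests."""
    spec = DesignSpec(
        n_male=3, n_female=3,
        sampling_times=(0.33, 0.75, 1.25, 2.0, 3.0, 4.0, 6.0, 12.0, 24.0),
    )
    return simulate_study(ffm_model, spec, np.random.default_rng(7))


@pytest.fixture(scope="session")
def default_study(ffm_model):
    """A full-design study (24 subjects, 2 occasions, nominal grid)."""
    return simulate_study(ffm_model, DesignSpec(), np.random.default_rng(42))
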