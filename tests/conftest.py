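import numpy as np
import pytest

from cobci import synth


@pytest.fixture(scope="session")
def small_cohort():
    """Three decodable subjects, 30 trials/condition: fast shared fixture."""
    config = synth.SimConfig(n_subjects=3, trials_per_condition=30, seed=42)
    profiles = synth.default_profiles(3, seed=42, noise_sd_uv=3.0)
    return config, profiles, synth.simulate_cohort(config, profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
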