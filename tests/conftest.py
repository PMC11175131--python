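import numpy as np
import pytest

from gaitstab.presets import default_presets
from gaitstab.synthetic import ParticipantProfile, synth_trial


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture()
def profile():
    return ParticipantProfile(
        participant_id="P000",
        failure_count=120,
        step_frequency=1.9,
        base_amplitude=3.0,
    )


@pytest.fixture()
def quiet_profile():
    """Noise-free walker for ground-truth recovery checks."""
    return ParticipantProfile(
        participant_id="P000",
        failure_count=120,
        step_frequency=1.9,
        base_amplitude=3.0,
        noise_scale=0.0,
    )


@pytest.fixture()
def clean_trial(quiet_profile, presets):
    """Unperturbed, noise-free 10-cycle trial."""
    rng = np.random.default_rng(42)
    return synth_trial(
        quiet_profile, presets["A"], 0, 10, rng, injected_magnitude=0.0
    )
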