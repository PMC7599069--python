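import numpy as np
import pytest

from saccvig.config import CONDITIONS, SimulationConfig
from saccvig.saccades import detect_session
from saccvig.synth import simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def zero_effects():
    return {c: 0.0 for c in CONDITIONS}


@pytest.fixture
def quiet_config():
    """All perturbations and injected effects off: deterministic saccades."""
    return SimulationConfig(
        trials_per_condition=16,
        noise_scale=0.0,
        feedback_gain=0.0,
        blink_rate=0.0,
        microsaccade_rate=0.0,
        tremor_amp=0.0,
        drift_speed=0.0,
        pupil_noise_sd=0.0,
        amplitude_sd=0.4,
        vigour_effect_sd=0.0,
        vigour_effects=zero_effects(),
    )


@pytest.fixture
def small_config():
    """Default generator at a reduced trial count."""
    return SimulationConfig(trials_per_condition=16)


@pytest.fixture(scope="session")
def default_session():
    """One default-noise simulated session with its ground truth and saccades."""
    cfg = SimulationConfig(trials_per_condition=16)
    rec, truth = simulate_session(cfg, "P01", "ON", np.random.default_rng(11))
    return cfg, rec, truth, detect_session(rec)


@pytest.fixture(scope="session")
def quiet_session():
    """A perturbation-free session (and its detections) shared across tests."""
    cfg = SimulationConfig(
        trials_per_condition=16,
        noise_scale=0.0,
        feedback_gain=0.0,
        blink_rate=0.0,
        microsaccade_rate=0.0,
        tremor_amp=0.0,
        drift_speed=0.0,
        pupil_noise_sd=0.0,
        amplitude_sd=0.4,
        vigour_effect_sd=0.0,
        vigour_effects={c: 0.0 for c in CONDITIONS},
    )
    rec, truth = simulate_session(cfg, "P01", "ON", np.random.default_rng(21))
    return cfg, rec, truth, detect_session(rec)
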