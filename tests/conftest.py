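import pytest
from hypothesis import HealthCheck, settings

import fpcontrol as fpc

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

G = 9.81


@pytest.fixture(scope="session")
def trial60():
    """Steady normal-speed trial, 60 strides, no EMG (shared, read-only)."""
    cfg = fpc.make_config("normal", "steady", seed=7, n_strides=60,
                          include_emg=False)
    trial, truth = fpc.simulate_trial(cfg)
    return cfg, trial, truth


@pytest.fixture(scope="session")
def events60(trial60):
    _, trial, _ = trial60
    return fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                   body_weight_n=trial.body_mass * G)


@pytest.fixture(scope="session")
def records60(trial60, events60):
    cfg, trial, _ = trial60
    return fpc.extract_step_records(trial, events60, n_strides=cfg.n_strides,
                                    include_emg=False)


@pytest.fixture(scope="session")
def emg_trial():
    """Smaller trial with EMG channels for the muscle-model path."""
    cfg = fpc.make_config("normal", "steady", seed=21, n_strides=80)
    trial, truth = fpc.simulate_trial(cfg)
    events = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                     body_weight_n=trial.body_mass * G)
    records = fpc.extract_step_records(trial, events, n_strides=cfg.n_strides)
    return cfg, trial, truth, records
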