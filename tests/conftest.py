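import numpy as np
import pytest

from rpeacc import behavior, encoding_glm, synthetic


@pytest.fixture(scope="session")
def expert_session():
    """Small expert-like session with planted ground truth."""
    return synthetic.generate_session(
        synthetic.expert_config(n_trials=15, seed=11, mean_toward_errors=2.5))


@pytest.fixture(scope="session")
def naive_session():
    return synthetic.generate_session(
        synthetic.naive_config(n_trials=15, seed=12))


@pytest.fixture(scope="session")
def split_session():
    return synthetic.generate_session(
        synthetic.split_config(n_trials=15, seed=13, mean_toward_errors=2.0))


@pytest.fixture(scope="session")
def ir_session():
    return synthetic.generate_session(
        synthetic.ir_config(n_trials=30, seed=14))


@pytest.fixture(scope="session")
def expert_design(expert_session):
    session, _ = expert_session
    events = behavior.detect_errors(session)
    dm = encoding_glm.build_design_matrix(events, session)
    return session, events, dm


@pytest.fixture(scope="session")
def small_population():
    """A compact planted population on an error-rich session, so every
    n = 1..6 accumulation level has enough onsets to be identifiable."""
    cfg = synthetic.expert_config(n_trials=20, seed=21,
                                  mean_toward_errors=4.5)
    session, _ = synthetic.generate_session(cfg)
    events = behavior.detect_errors(session)
    dm = encoding_glm.build_design_matrix(events, session)
    spec = synthetic.PopulationSpec(n_per_error_step=2, n_object_velocity=4,
                                    n_joystick_velocity=4, n_time=2,
                                    n_noise=6)
    traces, truth, _ = synthetic.generate_neurons(session, spec, cfg, dm=dm)
    return session, events, dm, traces, truth
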