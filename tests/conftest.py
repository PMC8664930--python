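import numpy as np
import pytest
from hypothesis import settings

from conjlearn import rl, task

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def space():
    return task.build_stimulus_space()


@pytest.fixture(scope="session")
def schedule():
    return task.make_default_schedule()


@pytest.fixture(scope="session")
def fc1_session(schedule):
    """One simulated mixed feature+conjunction learner with latent traces."""
    spec = rl.RLModelSpec("fc1", "chosen", True)
    params = rl.RLParams(
        alpha_rew=0.35, alpha_unr=0.2, d=0.02, w_f=6.0, w_c=6.0, bias=0.0
    )
    return rl.simulate_agent(schedule, spec, params, seed=11, record_values=True)


@pytest.fixture(scope="session")
def feature_session(schedule):
    """One simulated feature-only learner (choice weight concentrated on the
    informative dimension, as fitted feature-based learners show)."""
    spec = rl.RLModelSpec("feature", "chosen", True)
    params = rl.RLParams(
        alpha_rew=0.35, alpha_unr=0.2, d=0.02,
        w_f=np.array([7.0, 1.5, 1.5]), bias=0.0,
    )
    return rl.simulate_agent(schedule, spec, params, seed=12, record_values=True)
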