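import numpy as np
import pytest

from valencerl import (
    ModelParams,
    SessionConfig,
    generate_session_trials,
    get_model_kind,
    simulate_agent,
)

ALL_KINDS = (
    "q_learning",
    "actor_only",
    "actor_critic_no_beta",
    "actor_critic_free_beta",
)


def make_random_log(kind_name, n_trials=20, seed=0, phi=0.0):
    """A short session played by a randomly parameterized agent."""
    rng = np.random.default_rng(seed)
    params = ModelParams(
        alpha=rng.uniform(0.1, 0.9),
        alpha_a_plus=rng.uniform(0.1, 0.9),
        alpha_a_minus=rng.uniform(0.1, 0.9),
        alpha_c_plus=rng.uniform(0.1, 0.9),
        alpha_c_minus=rng.uniform(0.1, 0.9),
        beta=rng.uniform(0.5, 6.0),
        phi=phi,
    )
    kind = get_model_kind(kind_name.removesuffix("+kernel"))
    trials = generate_session_trials(SessionConfig(), rng)[:n_trials]
    log = simulate_agent(kind, params, trials, rng_seed=rng)
    return params, log


@pytest.fixture(scope="session")
def q_learning_log():
    """A full 160-trial session simulated from a mid-range Q-learner."""
    params = ModelParams(alpha=0.3, beta=3.0)
    rng = np.random.default_rng(42)
    trials = generate_session_trials(SessionConfig(), rng)
    return params, simulate_agent(get_model_kind("q_learning"), params, trials,
                                  rng_seed=rng, subject_id="qsubj")
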