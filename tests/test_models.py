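"""Model updates, softmax choice, and trajectory invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valencerl import (
    ModelParams,
    ModelState,
    choice_prob,
    get_model_kind,
    simulate_agent,
    step,
    with_perseveration,
)
from valencerl.models import (
    UsageError,
    actor_update,
    critic_update,
    prediction_error_q,
    q_update,
)
from valencerl.task import STIMULI, SessionConfig, generate_session_trials

from conftest import ALL_KINDS

S1, S3 = STIMULI["S1"], STIMULI["S3"]


class TestUpdateRules:
    @pytest.mark.parametrize("q0, o, expected", [
        (0.0, 1, 1.0),       # zero-initial identity
        (0.7, 0.7, 0.0),     # converged
        (0.4, -1, -1.4),     # direct evaluation of o - Q
    ])
    def test_prediction_error(self, q0, o, expected):
        state = ModelState()
        state.Q[0, 0] = q0
        assert prediction_error_q(state, S1, "A", o) == pytest.approx(expected)

    def test_q_update_valence_split(self):
        kind = get_model_kind("actor_only")
        state = ModelState()
        q_update(state, S1, "A", 1.0, ModelParams(alpha_a_plus=0.5), kind)
        assert state.Q[0, 0] == pytest.approx(0.5)
        state.Q[0, 0] = 0.5
        q_update(state, S1, "A", -1.5, ModelParams(alpha_a_minus=0.2), kind)
        assert state.Q[0, 0] == pytest.approx(0.2)
        # unchosen action and other stimuli untouched
        assert np.all(state.Q[1:] == 0) and state.Q[0, 1] == 0

    def test_q_update_zero_rate_is_identity(self):
        kind = get_model_kind("q_learning")
        state = ModelState()
        q_update(state, S1, "A", 5.0, ModelParams(alpha=0.0), kind)
        assert np.all(state.Q == 0)

    def test_q_update_rejects_critic_kinds(self):
        with pytest.raises(UsageError):
            q_update(ModelState(), S1, "A", 1.0, ModelParams(),
                     get_model_kind("actor_critic_free_beta"))

    @pytest.mark.parametrize("v0, o, rate_plus, rate_minus, dv, dd", [
        (0.0, 1, 0.3, 0.1, 0.3, 1.0),
        (0.5, 0.5, 0.3, 0.1, 0.5, 0.0),
        (0.3, -1, 0.3, 0.1, 0.17, -1.3),
    ])
    def test_critic_update(self, v0, o, rate_plus, rate_minus, dv, dd):
        state = ModelState()
        state.V[0] = v0
        params = ModelParams(alpha_c_plus=rate_plus, alpha_c_minus=rate_minus)
        _, delta = critic_update(state, S1, o, params)
        assert delta == pytest.approx(dd)
        assert state.V[0] == pytest.approx(dv)

    def test_critic_update_rejects_q_learning(self):
        with pytest.raises(UsageError):
            critic_update(ModelState(), S1, 1, ModelParams(),
                          model_kind=get_model_kind("q_learning"))

    @pytest.mark.parametrize("p0, delta, rp, rm, expected", [
        (0.0, 1.0, 0.4, 0.25, 0.4),
        (0.4, -2.0, 0.4, 0.25, -0.1),
        (0.7, 0.5, 0.0, 0.0, 0.7),
    ])
    def test_actor_update(self, p0, delta, rp, rm, expected):
        state = ModelState()
        state.P[0, 0] = p0
        actor_update(state, S1, "A", delta,
                     ModelParams(alpha_a_plus=rp, alpha_a_minus=rm))
        assert state.P[0, 0] == pytest.approx(expected)


class TestChoiceProb:
    def test_symmetry_and_noise_limit(self):
        kind = get_model_kind("q_learning")
        state = ModelState()
        assert choice_prob(state, S1, ModelParams(beta=1), kind) == (0.5, 0.5)
        state.Q[0] = [2.0, -1.0]
        assert choice_prob(state, S1, ModelParams(beta=0.0), kind) == (0.5, 0.5)

    def test_closed_form(self):
        kind = get_model_kind("q_learning")
        state = ModelState()
        state.Q[0] = [1.0, 0.0]
        p_a, p_b = choice_prob(state, S1, ModelParams(beta=1.0), kind)
        assert p_a == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert p_a + p_b == pytest.approx(1.0)

    def test_actor_critic_reads_preferences_not_q(self):
        kind = get_model_kind("actor_critic_free_beta")
        state = ModelState()
        state.Q[0] = [5.0, 0.0]  # must be ignored
        state.P[0] = [0.0, 1.0]
        p_a, _ = choice_prob(state, S1, ModelParams(beta=2.0), kind)
        assert p_a == pytest.approx(1 / (1 + np.exp(2.0)))


class TestStep:
    def test_q_learning_no_feedback_only_moves_choice_kernel(self):
        kind = get_model_kind("q_learning")
        state = step(kind, ModelState(), S1, "B", 0, ModelParams(alpha=0.5))
        assert np.all(state.Q == 0) and np.all(state.V == 0)
        assert state.C[0].tolist() == [0.0, 1.0]

    def test_actor_critic_shares_delta(self):
        kind = get_model_kind("actor_critic_free_beta")
        params = ModelParams(alpha_c_plus=0.3, alpha_a_plus=0.4)
        state = step(kind, ModelState(), S3, "A", 1, params)
        # delta = 1 - V = 1 for both updates
        assert state.V[2] == pytest.approx(0.3)
        assert state.P[2, 0] == pytest.approx(0.4)
        assert np.all(state.Q == 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(UsageError):
            get_model_kind("deep_q_network")

    def test_no_feedback_switch(self):
        kind = get_model_kind("q_learning")
        params = ModelParams(alpha=0.5)
        st1 = step(kind, ModelState(), S1, "A", 1, params)
        st1 = step(kind, st1, S1, "A", 0, params, update_on_no_feedback=False)
        assert st1.Q[0, 0] == pytest.approx(0.5)  # o=0 trial skipped


class TestSimulation:
    def test_noise_limit_is_chance(self):
        kind = get_model_kind("q_learning")
        trials = generate_session_trials(
            SessionConfig(), np.random.default_rng(0)
        )
        log = simulate_agent(kind, ModelParams(alpha=0.5, beta=0.0), trials,
                             rng_seed=1)
        p_a = np.mean([t.response == "A" for t in log.trials])
        assert abs(p_a - 0.5) < 3 * 0.5 / np.sqrt(160)

    def test_learning_trend_with_sharp_softmax(self):
        kind = get_model_kind("q_learning")
        params = ModelParams(alpha=0.5, beta=8.0)
        first, last = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            trials = generate_session_trials(SessionConfig(), rng)
            log = simulate_agent(kind, params, trials, rng_seed=rng)
            opt = [t.optimal for t in log.trials]
            first.append(np.mean(opt[:40]))
            last.append(np.mean(opt[-40:]))
        assert np.mean(last) > np.mean(first) + 0.1

    def test_same_seed_same_responses(self):
        kind = get_model_kind("actor_critic_free_beta")
        params = ModelParams(beta=2.0)
        trials = generate_session_trials(SessionConfig(),
                                         np.random.default_rng(3))
        a = simulate_agent(kind, params, trials, rng_seed=7)
        b = simulate_agent(kind, params, trials, rng_seed=7)
        assert [t.response for t in a.trials] == [t.response for t in b.trials]


# -- property tests ----------------------------------------------------------

rates = st.floats(0.0, 1.0)
outcomes = st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=60)
actions = st.lists(st.sampled_from(["A", "B"]), min_size=60, max_size=60)
stims = st.lists(st.sampled_from(list(STIMULI)), min_size=60, max_size=60)


@settings(max_examples=50, derandomize=True)
@given(
    kind_name=st.sampled_from(ALL_KINDS),
    ap=rates, am=rates, cp=rates, cm=rates, a=rates,
    beta=st.floats(0.0, 20.0),
    outs=outcomes, acts=actions, ss=stims,
)
def test_probabilities_conserve_and_values_stay_bounded(
    kind_name, ap, am, cp, cm, a, beta, outs, acts, ss
):
    """p(A)+p(B)=1 every trial; zero-initialized Q and V stay in [-1,1]
    for any rates in [0,1] and outcomes in {-1,0,1} (convex bound)."""
    kind = get_model_kind(kind_name)
    params = ModelParams(alpha=a, alpha_a_plus=ap, alpha_a_minus=am,
                         alpha_c_plus=cp, alpha_c_minus=cm, beta=beta)
    state = ModelState()
    for o, act, sid in zip(outs, acts, ss):
        p_a, p_b = choice_prob(state, STIMULI[sid], params, kind)
        assert 0.0 < p_a < 1.0
        assert p_a + p_b == pytest.approx(1.0, abs=1e-12)
        state = step(kind, state, STIMULI[sid], act, o, params)
        assert np.all(np.abs(state.Q) <= 1 + 1e-12)
        assert np.all(np.abs(state.V) <= 1 + 1e-12)


@settings(max_examples=30, derandomize=True)
@given(a=rates, outs=outcomes, acts=actions, ss=stims)
def test_valence_split_with_equal_rates_equals_single_rate(a, outs, acts, ss):
    """actor_only with alpha+ = alpha- reproduces the q_learning
    trajectory with that single alpha, trial for trial."""
    split = get_model_kind("actor_only")
    single = get_model_kind("q_learning")
    ps = ModelParams(alpha_a_plus=a, alpha_a_minus=a, beta=1.0)
    pq = ModelParams(alpha=a, beta=1.0)
    s1, s2 = ModelState(), ModelState()
    for o, act, sid in zip(outs, acts, ss):
        s1 = step(split, s1, STIMULI[sid], act, o, ps)
        s2 = step(single, s2, STIMULI[sid], act, o, pq)
        np.testing.assert_allclose(s1.Q, s2.Q, atol=1e-14)


def test_perseveration_biases_toward_previous_choice():
    """With phi > 0 and beta = 0, the repeat probability exceeds 0.5."""
    kind = with_perseveration(get_model_kind("q_learning"))
    params = ModelParams(alpha=0.5, beta=0.0, phi=1.5)
    state = step(kind, ModelState(), S1, "B", 0, params)
    p_a, p_b = choice_prob(state, S1, params, kind)
    assert p_b > 0.5
    assert p_b == pytest.approx(1 / (1 + np.exp(-1.5)))
    # phi is inert on a kind that does not free it
    base = get_model_kind("q_learning")
    p_a2, _ = choice_prob(state, S1, params, base)
    assert p_a2 == 0.5
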