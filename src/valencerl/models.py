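"""Trial-by-trial learning models with valence-split learning rates.

Four model kinds are implemented:

``q_learning``
    Stimulus-action values Q(s,a) updated with a single learning rate
    alpha applied to prediction errors of either sign; softmax choice
    with noise beta. 2 free parameters.
``actor_only``
    Like Q-learning but with separate learning rates for positive
    (alpha_a_plus) and negative (alpha_a_minus) prediction errors on the
    stimulus-action values. 3 free parameters.
``actor_critic_no_beta`` / ``actor_critic_free_beta``
    A critic learns stimulus values V(s) with valence-split rates
    alpha_c_plus/alpha_c_minus from delta = o - V(s); the same delta
    trains actor preferences P(s,a) for the chosen action with
    alpha_a_plus/alpha_a_minus. Choice is a softmax over P. The no-beta
    variant fixes beta = 1 (4 free parameters); the free-beta variant
    frees it (5).

Outcomes are coded o in {+1, 0, -1} = sign(feedback points); beta
absorbs the point scale. All softmaxes optionally include a
perseveration kernel phi * (C(s,A) - C(s,B)), where C marks the choice
made on the previous presentation of the same stimulus; phi is fixed at
0 unless a "+kernel" model variant frees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .task import (
    ACTION_INDEX,
    CATEGORIES,
    STIMULUS_IDS,
    STIMULUS_INDEX,
    SessionConfig,
    SessionLog,
    StimulusSpec,
    TrialRecord,
    feedback_for,
    generate_session_trials,
)

N_STIM = len(STIMULUS_IDS)
N_ACTIONS = len(CATEGORIES)


class UsageError(RuntimeError):
    """An operation was applied to a model kind it does not belong to."""


@dataclass(frozen=True)
class ModelKind:
    """A member of the model family.

    ``free_parameters`` is the ordered tuple optimized during fitting;
    anything else is held at its fixed value (notably beta = 1 for the
    no-beta actor-critic and phi = 0 everywhere unless freed).
    """

    name: str
    free_parameters: tuple[str, ...]
    uses_critic: bool
    fixed_beta: float | None = None

    @property
    def k(self) -> int:
        """Number of free parameters (the BIC k)."""
        return len(self.free_parameters)


MODEL_KINDS: dict[str, ModelKind] = {
    "q_learning": ModelKind("q_learning", ("alpha", "beta"), uses_critic=False),
    "actor_only": ModelKind(
        "actor_only", ("alpha_a_plus", "alpha_a_minus", "beta"), uses_critic=False
    ),
    "actor_critic_no_beta": ModelKind(
        "actor_critic_no_beta",
        ("alpha_c_plus", "alpha_c_minus", "alpha_a_plus", "alpha_a_minus"),
        uses_critic=True,
        fixed_beta=1.0,
    ),
    "actor_critic_free_beta": ModelKind(
        "actor_critic_free_beta",
        ("alpha_c_plus", "alpha_c_minus", "alpha_a_plus", "alpha_a_minus", "beta"),
        uses_critic=True,
    ),
}


def get_model_kind(name: str) -> ModelKind:
    try:
        return MODEL_KINDS[name]
    except KeyError:
        raise UsageError(f"unknown model kind {name!r}") from None


def with_perseveration(kind: ModelKind) -> ModelKind:
    """Variant of a model kind with the perseveration weight phi freed."""
    if "phi" in kind.free_parameters:
        return kind
    return replace(
        kind,
        name=kind.name + "+kernel",
        free_parameters=kind.free_parameters + ("phi",),
    )


@dataclass(frozen=True)
class ModelParams:
    """Parameter values for any model kind; unused fields are ignored.

    Learning rates live in [0, 1]; beta >= 0 scales value differences in
    the softmax (beta = 0 is chance responding); phi > 0 perseverates,
    phi < 0 alternates.
    """

    alpha: float = 0.1
    alpha_a_plus: float = 0.1
    alpha_a_minus: float = 0.1
    alpha_c_plus: float = 0.1
    alpha_c_minus: float = 0.1
    beta: float = 1.0
    phi: float = 0.0

    def validate(self) -> None:
        for name in ("alpha", "alpha_a_plus", "alpha_a_minus",
                     "alpha_c_plus", "alpha_c_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")

    def for_kind(self, kind: ModelKind) -> "ModelParams":
        """Apply the kind's fixed values (beta = 1 for the no-beta variant)."""
        out = self
        if kind.fixed_beta is not None and "beta" not in kind.free_parameters:
            out = replace(out, beta=kind.fixed_beta)
        if "phi" not in kind.free_parameters and out.phi != 0.0:
            out = replace(out, phi=0.0)
        return out


@dataclass
class ModelState:
    """Trial-evolving tables, all zero-initialized.

    Q: stimulus x action values (q_learning / actor_only).
    V: critic stimulus values (actor-critic kinds).
    P: actor stimulus x action preferences (actor-critic kinds).
    C: one-hot last-choice indicator per stimulus (all-zero before the
    first presentation of that stimulus).
    """

    Q: np.ndarray = field(default_factory=lambda: np.zeros((N_STIM, N_ACTIONS)))
    V: np.ndarray = field(default_factory=lambda: np.zeros(N_STIM))
    P: np.ndarray = field(default_factory=lambda: np.zeros((N_STIM, N_ACTIONS)))
    C: np.ndarray = field(default_factory=lambda: np.zeros((N_STIM, N_ACTIONS)))

    def copy(self) -> "ModelState":
        return ModelState(self.Q.copy(), self.V.copy(), self.P.copy(), self.C.copy())


def outcome_code(feedback_points: float) -> int:
    """Code feedback points as o in {+1, 0, -1} (the sign)."""
    return int(np.sign(feedback_points))


def _stim_index(stimulus) -> int:
    sid = stimulus.id if isinstance(stimulus, StimulusSpec) else stimulus
    return STIMULUS_INDEX[sid]


def _action_index(action: str) -> int:
    return ACTION_INDEX[action]


def prediction_error_q(state: ModelState, stimulus, action: str, outcome: int) -> float:
    """delta = o - Q(s, chosen action)."""
    return outcome - state.Q[_stim_index(stimulus), _action_index(action)]


def q_update(
    state: ModelState,
    stimulus,
    action: str,
    delta: float,
    params: ModelParams,
    model_kind: ModelKind,
) -> ModelState:
    """Increment the chosen action's Q by the sign-appropriate rate times delta.

    q_learning applies the single rate ``alpha`` to both signs;
    actor_only applies ``alpha_a_plus`` when delta > 0 and
    ``alpha_a_minus`` when delta < 0. Mutates and returns ``state``.
    """
    if model_kind.uses_critic:
        raise UsageError("q_update applies to q_learning/actor_only kinds only")
    if model_kind.name == "q_learning":
        rate = params.alpha
    else:
        rate = params.alpha_a_plus if delta > 0 else params.alpha_a_minus
    state.Q[_stim_index(stimulus), _action_index(action)] += rate * delta
    return state


def critic_update(
    state: ModelState,
    stimulus,
    outcome: int,
    params: ModelParams,
    model_kind: ModelKind | None = None,
) -> tuple[ModelState, float]:
    """Critic step: delta = o - V(s); V(s) += alpha_c(+/-) * delta.

    Returns the updated state and the delta, which is also conveyed to
    the actor. Pass ``model_kind`` to assert the kind actually has a
    critic.
    """
    if model_kind is not None and not model_kind.uses_critic:
        raise UsageError(f"{model_kind.name} has no critic")
    s = _stim_index(stimulus)
    delta = outcome - state.V[s]
    rate = params.alpha_c_plus if delta > 0 else params.alpha_c_minus
    state.V[s] += rate * delta
    return state, delta


def actor_update(
    state: ModelState, stimulus, choice: str, delta: float, params: ModelParams
) -> ModelState:
    """Actor step: P(s, chosen) += alpha_a(+/-) * delta."""
    rate = params.alpha_a_plus if delta > 0 else params.alpha_a_minus
    state.P[_stim_index(stimulus), _action_index(choice)] += rate * delta
    return state


def choice_prob(
    state: ModelState, stimulus, params: ModelParams, model_kind: ModelKind
) -> tuple[float, float]:
    """Softmax probability of choosing A and B for this stimulus.

    p(A) = 1 / (1 + exp[-beta (x_A - x_B) - phi (C_A - C_B)]) where x is
    Q for q_learning/actor_only and the actor preference P for the
    actor-critic kinds. Strictly inside (0, 1), p(A) + p(B) = 1.
    """
    params = params.for_kind(model_kind)
    s = _stim_index(stimulus)
    x = state.P[s] if model_kind.uses_critic else state.Q[s]
    z = params.beta * (x[0] - x[1]) + params.phi * (state.C[s, 0] - state.C[s, 1])
    p_a = 1.0 / (1.0 + np.exp(-z))
    return float(p_a), float(1.0 - p_a)


def step(
    model_kind: ModelKind,
    state: ModelState,
    stimulus,
    action: str,
    outcome: int,
    params: ModelParams,
    update_on_no_feedback: bool = True,
) -> ModelState:
    """Apply one trial's learning update in place and return the state.

    Actor-critic kinds run the critic then the actor with the same
    delta; the value kinds run the Q update. The last-choice indicator
    C(s, .) is then set one-hot at the chosen action. With
    ``update_on_no_feedback=False``, ambiguous no-feedback trials
    (o = 0) leave values untouched but still update C.
    """
    params = params.for_kind(model_kind)
    if update_on_no_feedback or outcome != 0:
        if model_kind.uses_critic:
            state, delta = critic_update(state, stimulus, outcome, params)
            state = actor_update(state, stimulus, action, delta, params)
        else:
            delta = prediction_error_q(state, stimulus, action, outcome)
            state = q_update(state, stimulus, action, delta, params, model_kind)
    s = _stim_index(stimulus)
    state.C[s, :] = 0.0
    state.C[s, _action_index(action)] = 1.0
    return state


def simulate_agent(
    model_kind: ModelKind,
    params: ModelParams,
    trials,
    rng_seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    group: str = "HC",
    update_on_no_feedback: bool = True,
) -> SessionLog:
    """Play a model generatively over pre-generated session trials.

    ``trials`` is a sequence of (block, StimulusSpec, correct_category)
    as produced by :func:`valencerl.task.generate_session_trials`. On
    each trial a response is sampled from the model's choice
    probability, feedback is delivered by the task's feedback matrix,
    and the state is updated. Deterministic given the seed. The top-up
    procedure is not applied here; use :class:`RLAgent` with
    :func:`valencerl.task.run_session` for a full session.
    """
    params.validate()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    state = ModelState()
    log = SessionLog(subject_id=subject_id, group=group)
    for i, (block, stim, correct_cat) in enumerate(trials, start=1):
        p_a, _ = choice_prob(state, stim, params, model_kind)
        resp = "A" if rng.random() < p_a else "B"
        points = feedback_for(stim, resp, correct_cat)
        state = step(
            model_kind, state, stim, resp, outcome_code(points), params,
            update_on_no_feedback=update_on_no_feedback,
        )
        log.trials.append(
            TrialRecord(
                block=block,
                trial=i,
                stimulus=stim.id,
                correct_category=correct_cat,
                response=resp,
                feedback_points=points,
                optimal=resp == stim.common_category,
            )
        )
    log.final_points = 500 + sum(t.feedback_points for t in log.trials)
    return log


class RLAgent:
    """Adapter exposing a learning model as a task agent.

    Holds its own ModelState and learns from the feedback it observes,
    so it can be handed to :func:`valencerl.task.run_session` (including
    the top-up phase, where learning continues but the trials are
    flagged and excluded from analysis).
    """

    def __init__(
        self,
        model_kind: ModelKind,
        params: ModelParams,
        update_on_no_feedback: bool = True,
    ):
        params.validate()
        self.kind = model_kind
        self.params = params
        self.update_on_no_feedback = update_on_no_feedback
        self.state = ModelState()

    def respond(self, stimulus: StimulusSpec, rng: np.random.Generator) -> str:
        p_a, _ = choice_prob(self.state, stimulus, self.params, self.kind)
        return "A" if rng.random() < p_a else "B"

    def observe(
        self, stimulus: StimulusSpec, response: str, feedback_points: int
    ) -> None:
        self.state = step(
            self.kind,
            self.state,
            stimulus,
            response,
            outcome_code(feedback_points),
            self.params,
            update_on_no_feedback=self.update_on_no_feedback,
        )
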