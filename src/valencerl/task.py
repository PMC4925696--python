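"""Probabilistic category-learning task with valence-split feedback.

The task presents one of four stimuli per trial and asks for a binary
category guess (A or B). Two stimuli are *positive-valence*: a correct
guess wins +25 points and an incorrect guess yields nothing. The other
two are *negative-valence*: an incorrect guess loses 25 points and a
correct guess yields nothing. Each stimulus belongs to its common
category on 80% of its trials, enforced as an exact 8-of-10 count per
block rather than i.i.d. sampling. A session is 4 blocks x 40 trials =
160 analyzable trials; sessions that end below the 500-point floor are
topped up with forced-correct filler trials (excluded from analysis)
until the tally reaches at least 525.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

CATEGORIES = ("A", "B")
STIMULUS_IDS = ("S1", "S2", "S3", "S4")

#: Stimulus id -> 0..3 index, shared with the model state tables.
STIMULUS_INDEX = {s: i for i, s in enumerate(STIMULUS_IDS)}
#: Category -> 0/1 action index.
ACTION_INDEX = {"A": 0, "B": 1}


class ProtocolError(ValueError):
    """An agent or log violated the task protocol (e.g. invalid response)."""


class ConfigurationError(ValueError):
    """A session configuration fails its invariants."""


@dataclass(frozen=True)
class StimulusSpec:
    """One of the four task stimuli.

    ``valence`` decides which feedback arm the stimulus belongs to
    (reward-on-correct vs punish-on-incorrect); ``common_category`` is
    the category sampled with probability ``p_common`` on each trial.
    """

    id: str
    valence: str  # "positive" | "negative"
    common_category: str  # "A" | "B"
    p_common: float = 0.8

    @property
    def rare_category(self) -> str:
        return "B" if self.common_category == "A" else "A"


def build_stimulus_set() -> list[StimulusSpec]:
    """Return the fixed four-stimulus set.

    S1/S2 are positive-valence, S3/S4 negative-valence; S1/S3 have
    common category A, S2/S4 have common category B, all at 80%.
    """
    return [
        StimulusSpec("S1", "positive", "A"),
        StimulusSpec("S2", "positive", "B"),
        StimulusSpec("S3", "negative", "A"),
        StimulusSpec("S4", "negative", "B"),
    ]


STIMULI = {s.id: s for s in build_stimulus_set()}


@dataclass(frozen=True)
class SessionConfig:
    """Counts and point rules for one session.

    Defaults reproduce the administered task: 4 blocks, 10 repetitions
    of each stimulus per block (8 with the common category, 2 with the
    rare one), +-25 point feedback, a 500-point starting stake, and the
    top-up rule (below 500 after the main trials -> filler trials until
    at least 525).
    """

    n_blocks: int = 4
    reps_per_stimulus_per_block: int = 10
    common_outcome_reps: int = 8
    reward_points: int = 25
    punishment_points: int = -25
    start_points: int = 500
    topup_floor: int = 500
    topup_target: int = 525

    def __post_init__(self) -> None:
        if self.common_outcome_reps > self.reps_per_stimulus_per_block:
            raise ConfigurationError(
                "common_outcome_reps cannot exceed reps_per_stimulus_per_block"
            )
        if min(self.n_blocks, self.reps_per_stimulus_per_block,
               self.common_outcome_reps) < 0:
            raise ConfigurationError("counts must be nonnegative")

    @property
    def n_main_trials(self) -> int:
        return self.n_blocks * self.reps_per_stimulus_per_block * len(STIMULUS_IDS)


@dataclass(frozen=True)
class TrialRecord:
    """One administered trial.

    ``optimal`` records whether the response matched the stimulus's
    common category, irrespective of the sampled outcome. ``topup``
    flags post-session filler trials, which are excluded from all
    fitting and metrics.
    """

    block: int
    trial: int
    stimulus: str
    correct_category: str
    response: str
    feedback_points: int
    optimal: bool
    topup: bool = False


@dataclass
class SessionLog:
    """Ordered trial records for one subject plus the final point tally."""

    subject_id: str
    group: str
    trials: list[TrialRecord] = field(default_factory=list)
    final_points: int = 0

    @property
    def main_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.topup]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "block": t.block,
                "trial": t.trial,
                "stimulus": t.stimulus,
                "valence": STIMULI[t.stimulus].valence,
                "correct_category": t.correct_category,
                "response": t.response,
                "feedback_points": t.feedback_points,
                "optimal": t.optimal,
                "topup": t.topup,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def session_from_frame(frame: pd.DataFrame) -> SessionLog:
    """Rebuild a SessionLog from its tidy one-row-per-trial frame."""
    if frame.empty:
        raise ProtocolError("empty trial frame")
    subject_id = str(frame["subject_id"].iloc[0])
    group = str(frame["group"].iloc[0])
    trials = []
    tally = None
    for row in frame.itertuples(index=False):
        if row.response not in CATEGORIES:
            raise ProtocolError(f"invalid response {row.response!r}")
        trials.append(
            TrialRecord(
                block=int(row.block),
                trial=int(row.trial),
                stimulus=str(row.stimulus),
                correct_category=str(row.correct_category),
                response=str(row.response),
                feedback_points=int(row.feedback_points),
                optimal=bool(row.optimal),
                topup=bool(row.topup),
            )
        )
    tally = 500 + sum(t.feedback_points for t in trials)
    return SessionLog(subject_id, group, trials, final_points=tally)


def sessions_to_csv(logs: Sequence[SessionLog], path) -> None:
    """Write session logs as one tidy UTF-8 CSV (one row per trial)."""
    pd.concat([log.to_frame() for log in logs], ignore_index=True).to_csv(
        path, index=False
    )


def sessions_from_csv(path) -> list[SessionLog]:
    frame = pd.read_csv(path)
    return [
        session_from_frame(sub)
        for _, sub in frame.groupby("subject_id", sort=False)
    ]


def feedback_for(stimulus: StimulusSpec, response: str, correct_category: str) -> int:
    """Points awarded for a response, per the valence-split feedback matrix.

    Positive-valence stimuli: +25 if correct, 0 if incorrect.
    Negative-valence stimuli: 0 if correct, -25 if incorrect.
    The two zero outcomes are observationally identical (ambiguous
    no-feedback).
    """
    if response not in CATEGORIES or correct_category not in CATEGORIES:
        raise ProtocolError("response and correct_category must be 'A' or 'B'")
    correct = response == correct_category
    if stimulus.valence == "positive":
        return 25 if correct else 0
    return 0 if correct else -25


def generate_block(
    config: SessionConfig, rng: np.random.Generator
) -> list[tuple[StimulusSpec, str]]:
    """One block of (stimulus, sampled correct category) pairs.

    Each stimulus appears ``reps_per_stimulus_per_block`` times, exactly
    ``common_outcome_reps`` of them with its common category; the trial
    order is a uniform shuffle.
    """
    pairs: list[tuple[StimulusSpec, str]] = []
    for stim in build_stimulus_set():
        n_common = config.common_outcome_reps
        n_rare = config.reps_per_stimulus_per_block - n_common
        pairs.extend((stim, stim.common_category) for _ in range(n_common))
        pairs.extend((stim, stim.rare_category) for _ in range(n_rare))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def generate_session_trials(
    config: SessionConfig, rng: np.random.Generator
) -> list[tuple[int, StimulusSpec, str]]:
    """All main trials for a session: (block, stimulus, correct_category)."""
    out = []
    for b in range(1, config.n_blocks + 1):
        out.extend((b, stim, cat) for stim, cat in generate_block(config, rng))
    return out


@runtime_checkable
class Agent(Protocol):
    """Choice policy queried once per trial.

    ``respond`` returns "A" or "B"; ``observe`` (optional on plain
    callables) receives the administered trial so stateful agents can
    learn. Agents draw any randomness from the rng they are handed so a
    session is fully reproducible from its seed.
    """

    def respond(self, stimulus: StimulusSpec, rng: np.random.Generator) -> str: ...

    def observe(
        self, stimulus: StimulusSpec, response: str, feedback_points: int
    ) -> None: ...


def _query(agent, stimulus: StimulusSpec, rng: np.random.Generator) -> str:
    if hasattr(agent, "respond"):
        resp = agent.respond(stimulus, rng)
    else:
        resp = agent(stimulus, rng)
    if resp not in CATEGORIES:
        raise ProtocolError(f"agent returned invalid response {resp!r}")
    return resp


def _notify(agent, stimulus, response, points) -> None:
    observe = getattr(agent, "observe", None)
    if observe is not None:
        observe(stimulus, response, points)


def run_session(
    agent,
    config: SessionConfig = SessionConfig(),
    rng_seed: int | np.random.Generator = 0,
    subject_id: str = "s01",
    group: str = "HC",
) -> SessionLog:
    """Administer a full session to an agent and return its log.

    Plays the generated blocks, accumulating points from
    ``start_points``. If the tally after the main trials is below
    ``topup_floor``, forced-correct top-up trials (positive-valence
    stimuli, +25 each, flagged ``topup=True``) are appended until the
    tally reaches ``topup_target``; those trials are excluded from all
    downstream analysis.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    log = SessionLog(subject_id=subject_id, group=group)
    tally = config.start_points
    trial_no = 0
    for block, stim, correct_cat in generate_session_trials(config, rng):
        trial_no += 1
        resp = _query(agent, stim, rng)
        points = feedback_for(stim, resp, correct_cat)
        if points > 0:
            points = config.reward_points
        elif points < 0:
            points = config.punishment_points
        tally += points
        log.trials.append(
            TrialRecord(
                block=block,
                trial=trial_no,
                stimulus=stim.id,
                correct_category=correct_cat,
                response=resp,
                feedback_points=points,
                optimal=resp == stim.common_category,
                topup=False,
            )
        )
        _notify(agent, stim, resp, points)

    if tally < config.topup_floor:
        # Forced-correct filler: the response is scored correct whatever
        # it is, a positive-valence stimulus is shown so the forced
        # correct outcome actually awards points, and the trial is
        # excluded from analysis.
        positive = [s for s in build_stimulus_set() if s.valence == "positive"]
        i = 0
        while tally < config.topup_target:
            stim = positive[i % len(positive)]
            i += 1
            trial_no += 1
            resp = _query(agent, stim, rng)
            tally += config.reward_points
            log.trials.append(
                TrialRecord(
                    block=config.n_blocks,
                    trial=trial_no,
                    stimulus=stim.id,
                    correct_category=resp,
                    response=resp,
                    feedback_points=config.reward_points,
                    optimal=resp == stim.common_category,
                    topup=True,
                )
            )
            _notify(agent, stim, resp, config.reward_points)

    log.final_points = tally
    return log


class FixedPolicyAgent:
    """Agent answering with a fixed response map (default: always optimal)."""

    def __init__(self, policy: Callable[[StimulusSpec], str] | None = None):
        self.policy = policy or (lambda stim: stim.common_category)

    def respond(self, stimulus: StimulusSpec, rng: np.random.Generator) -> str:
        return self.policy(stimulus)


def optimal_agent() -> FixedPolicyAgent:
    return FixedPolicyAgent()


def anti_optimal_agent() -> FixedPolicyAgent:
    """Pessimal policy: always the rare category (used to force top-up)."""
    return FixedPolicyAgent(lambda stim: stim.rare_category)
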