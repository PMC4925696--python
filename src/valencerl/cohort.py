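"""Synthetic cohorts with group-specific learning parameters.

Generates simulated GAD/SAD/PAD/HC subjects whose behavior reproduces,
qualitatively, the group-level dissociation the task was designed to
expose: GAD and SAD agents learn *better from negative feedback* than
PAD and HC agents, while all four groups are equivalent on positive
feedback. The generating model is the valence-split actor_only model;
the asymmetry is carried entirely by the negative-prediction-error
learning rate alpha_a_minus (elevated for GAD/SAD), with alpha_a_plus
and the softmax noise beta matched across groups. Calibration constants
were set once by simulation (see scripts/calibrate_cohort.py) and are
frozen here.

Every emitted session log is paired with its generating parameters
(`truth` table), so parameter recovery can be validated end to end.
Demographic columns (age, education, HAM-A anxiety score) are inert
metadata sampled to resemble a clinical sample; they drive nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .models import ModelParams, get_model_kind, RLAgent
from .task import SessionConfig, SessionLog, run_session

GROUPS = ("GAD", "SAD", "PAD", "HC")

#: Group sizes of the emulated clinical sample (total 73).
DEFAULT_GROUP_SIZES = {"GAD": 18, "SAD": 20, "PAD": 17, "HC": 18}

# Inert demographic profiles: (mean, sd) per column, per group.
_DEMOGRAPHICS = {
    "PAD": {"age": (41.52, 4.93), "education": (12.06, 2.84), "ham_a": (22.59, 3.98)},
    "SAD": {"age": (44.95, 4.27), "education": (12.15, 2.87), "ham_a": (24.50, 4.72)},
    "GAD": {"age": (42.11, 5.70), "education": (11.61, 3.25), "ham_a": (24.50, 2.98)},
    "HC": {"age": (43.50, 6.84), "education": (11.88, 3.22), "ham_a": (7.50, 3.20)},
}


@dataclass(frozen=True)
class ParamDist:
    """A per-parameter sampling distribution, truncated to stated bounds.

    kind "uniform": uniform on [lo, hi]. kind "truncnorm": normal with
    the given center/width truncated to [lo, hi]. A zero-width
    truncnorm degenerates to the constant ``center``.
    """

    kind: str  # "uniform" | "truncnorm"
    lo: float
    hi: float
    center: float = 0.0
    width: float = 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        if self.kind == "truncnorm":
            if self.width <= 0:
                return np.full(n, float(np.clip(self.center, self.lo, self.hi)))
            a = (self.lo - self.center) / self.width
            b = (self.hi - self.center) / self.width
            return stats.truncnorm.rvs(
                a, b, loc=self.center, scale=self.width, size=n, random_state=rng
            )
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class GroupSpec:
    """How one group's agents are parameterized."""

    name: str
    n_subjects: int
    generator_model: str = "actor_only"
    param_distributions: dict[str, ParamDist] = field(default_factory=dict)


def _shared_dists() -> dict[str, ParamDist]:
    # Positive-feedback learning and choice noise are matched across
    # groups: the group effect must come from alpha_a_minus alone. The
    # alpha_a_plus center sits at the crossover where the two ways
    # alpha_a_minus leaks into positive-stimulus behavior (decay of the
    # common action's value vs inflation of the rare action's value)
    # cancel, so group positive-feedback rates differ only by noise.
    return {
        "alpha_a_plus": ParamDist("truncnorm", 0.0, 1.0, center=0.40, width=0.05),
        "beta": ParamDist("truncnorm", 0.5, 12.0, center=4.0, width=0.3),
    }


def default_group_specs(
    group_sizes: dict[str, int] | None = None,
) -> list[GroupSpec]:
    """The frozen default calibration (see module docstring)."""
    sizes = {**DEFAULT_GROUP_SIZES, **(group_sizes or {})}
    high = ParamDist("truncnorm", 0.0, 1.0, center=0.35, width=0.06)
    low = ParamDist("truncnorm", 0.0, 1.0, center=0.12, width=0.04)
    specs = []
    for g in GROUPS:
        dists = _shared_dists()
        dists["alpha_a_minus"] = high if g in ("GAD", "SAD") else low
        specs.append(GroupSpec(name=g, n_subjects=sizes[g],
                               param_distributions=dists))
    return specs


def sample_group_params(
    group: GroupSpec, rng: np.random.Generator
) -> list[ModelParams]:
    """Draw per-subject generating parameters for one group."""
    kind = get_model_kind(group.generator_model)
    draws = {
        name: dist.sample(group.n_subjects, rng)
        for name, dist in group.param_distributions.items()
    }
    missing = set(kind.free_parameters) - set(draws)
    if missing:
        raise ValueError(f"no distribution for free parameter(s) {sorted(missing)}")
    out = []
    for i in range(group.n_subjects):
        params = ModelParams(**{name: float(vals[i]) for name, vals in draws.items()})
        params.validate()
        out.append(params)
    return out


@dataclass
class CohortData:
    """Session logs plus subject metadata and generating ground truth."""

    logs: list[SessionLog]
    subjects: pd.DataFrame  # subject_id, group, inert demographics
    truth: pd.DataFrame  # subject_id, group, generator model + parameters


def generate_cohort(
    group_specs: list[GroupSpec] | None = None,
    rng_seed: int = 0,
    config: SessionConfig = SessionConfig(),
) -> CohortData:
    """Simulate a full cohort, one complete session per subject.

    Each subject's agent plays the task through ``run_session`` (top-up
    rule included). Fully deterministic given the seed.
    """
    specs = group_specs if group_specs is not None else default_group_specs()
    rng = np.random.default_rng(rng_seed)
    logs, subj_rows, truth_rows = [], [], []
    sn = 0
    for spec in specs:
        kind = get_model_kind(spec.generator_model)
        params_list = sample_group_params(spec, rng)
        demo = _DEMOGRAPHICS.get(spec.name, {})
        for params in params_list:
            sn += 1
            sid = f"{spec.name.lower()}{sn:03d}"
            agent = RLAgent(kind, params)
            log = run_session(agent, config, rng_seed=rng,
                              subject_id=sid, group=spec.name)
            logs.append(log)
            row = {"subject_id": sid, "group": spec.name}
            for col, (mu, sd) in demo.items():
                row[col] = round(float(rng.normal(mu, sd)), 1)
            subj_rows.append(row)
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": spec.name,
                    "generator_model": kind.name,
                    **{p: getattr(params, p) for p in kind.free_parameters},
                }
            )
    return CohortData(
        logs=logs,
        subjects=pd.DataFrame(subj_rows),
        truth=pd.DataFrame(truth_rows),
    )


def load_cohort_config(path) -> list[GroupSpec]:
    """Read group specs from a YAML cohort config.

    Schema::

        groups:
          GAD:
            n_subjects: 18
            generator_model: actor_only
            params:
              alpha_a_minus: {kind: truncnorm, lo: 0, hi: 1, center: 0.35, width: 0.08}
              ...
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for name, g in raw["groups"].items():
        dists = {
            pname: ParamDist(**d) for pname, d in (g.get("params") or {}).items()
        }
        specs.append(
            GroupSpec(
                name=name,
                n_subjects=int(g["n_subjects"]),
                generator_model=g.get("generator_model", "actor_only"),
                param_distributions=dists,
            )
        )
    return specs
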