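# valencerl

Reinforcement-learning modelling of how people learn from reward versus
punishment, built for computational-psychiatry analyses of anxiety
disorders. The package covers the full pipeline around a probabilistic
category-learning task whose feedback structure *dissociates the two
valences*: two stimuli pay +25 points for correct guesses (and nothing
for errors), two lose 25 points for errors (and nothing for correct
guesses), so reward-seeking and punishment-avoidance are learned from
disjoint feedback channels. Because no patient data are distributable,
a first-class synthetic-cohort generator produces GAD/SAD/PAD/HC agents
with a known ground truth, making every stage of the pipeline —
simulation, fitting, model comparison, behavioral statistics —
exercisable end to end.

## The models

Choices on each trial (stimulus *s*, response *c* ∈ {A, B}) follow a
softmax over learned quantities *x*:

p(c=A | s) = 1 / (1 + exp[−β(x(s,A) − x(s,B)) − φ(C(s,A) − C(s,B))])

with noise β, optional perseveration weight φ, and C the one-hot
indicator of the previous choice for that stimulus. Outcomes are coded
o ∈ {+1, 0, −1}. Four model kinds differ in what *x* is and how it
learns from the prediction error δ:

| model | free parameters | learning |
|---|---|---|
| `q_learning` | α, β | δ = o − Q(s,c); Q(s,c) += αδ |
| `actor_only` | αa⁺, αa⁻, β | same, but αa⁺ for δ>0 and αa⁻ for δ<0 |
| `actor_critic_no_beta` | αc⁺, αc⁻, αa⁺, αa⁻ (β≡1) | critic: δ = o − V(s), V(s) += αc±δ; actor: P(s,c) += αa±δ |
| `actor_critic_free_beta` | + β | as above with β free |

Fitting is per-subject bounded maximum likelihood (multi-restart
L-BFGS-B on the teacher-forced replay negLLE = −Σₜ log Pr(rₜ)). Models
are compared by the criterion k·ln(n) − 2·ln(negLLE) (displayed
truncated to two decimals; note it *decreases* as negLLE grows), by the
conventional BIC = k·ln(n) + 2·negLLE, and by random-effects Bayesian
model selection (variational Dirichlet over per-subject −BIC/2
evidences, with Monte-Carlo exceedance probabilities).

## Worked example

```sh
python examples/02_fit_one_subject.py
```

```
true   alpha=0.350  beta=4.00  negLLE=62.80
fitted alpha=0.343  beta=4.04  negLLE=62.79  (chance 110.90)
```

A simulated Q-learner (α = 0.35, β = 4) plays the 160-trial session and
is refit from its choices alone: the recovered parameters land on the
generating values, and the fitted negLLE sits at (slightly below, being
the MLE) the truth's, far under the 160·ln 2 ≈ 110.90 chance ceiling.

`examples/03_compare_models.py` fits all four models to a cohort
generated from `q_learning` and prints the comparison table — the
selection concentrates on the true generator (expected posterior
probability 0.81, exceedance 0.999). `examples/04_cohort_signature.py`
generates the default 73-subject clinical cohort and prints its group
signature: block-4 negative-feedback accuracy GAD 0.90 / SAD 0.86 vs
PAD 0.81 / HC 0.81, with positive-feedback accuracy matched across
groups — anxiety-subtype-specific hypersensitivity to negative feedback,
with no group difference in reward learning.

## Layout

- `src/valencerl/task.py` — task design: stimuli, block construction, feedback matrix, session runner with the top-up rule
- `src/valencerl/models.py` — the model family, softmax choice, forward simulation
- `src/valencerl/fitting.py` — likelihood replay, per-subject and cohort MLE, parameter recovery
- `src/valencerl/comparison.py` — both BIC variants, random-effects Bayesian model selection
- `src/valencerl/cohort.py` — synthetic GAD/SAD/PAD/HC cohorts with ground-truth parameters
- `src/valencerl/metrics.py` — optimal-response accuracy tables, group summaries, chance tests
- `docs/methods.md` — modelling assumptions, calibration, and limitations
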