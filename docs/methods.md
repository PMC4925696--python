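# Methods

## Task model

The task is a probabilistic two-category classification with four
stimuli. Each stimulus belongs to its common category on 80% of its
presentations, realized as an *exact* 8-of-10 count per block per
stimulus (not i.i.d. sampling at 0.8): each of the 4 blocks holds 10
presentations of each stimulus, 8 with the common category and 2 with
the rare one, uniformly shuffled within the block. A session is
therefore 160 analyzable trials. Feedback is valence-split: the two
positive-valence stimuli pay +25 points when the response matches the
sampled category and give nothing otherwise; the two negative-valence
stimuli take 25 points on mismatches and give nothing otherwise. The
two "nothing" outcomes are observationally identical, which is what
makes the no-feedback event ambiguous to the learner. The *optimal*
response — the 80% category — is recorded per trial regardless of the
sampled outcome; behavioral accuracy means proportion optimal, not
proportion rewarded.

Sessions start from a 500-point stake. A session ending below 500 is
extended with top-up trials on which the response is scored correct
whatever it is; these continue until the tally reaches at least 525 and
are flagged and excluded from every downstream computation. Because the
original protocol does not say which stimuli appear on top-up trials,
we present positive-valence stimuli (alternating) so that a forced
"correct" outcome actually awards +25 — the only choice under which the
tally provably reaches the target (a forced-correct negative-valence
trial awards nothing). Since every point movement is ±25 from a
multiple of 25, a topped-up session always ends at exactly 525. The
practice phase and inter-trial timing are not modelled; the package is
an analysis engine, not a stimulus presenter.

## Learning models

All models code outcomes as o = sign(points) ∈ {+1, 0, −1}; the softmax
noise β absorbs the point scale, keeping β comparable across models.
No-feedback trials drive updates as o = 0 by default (δ = 0 − value),
which acts as a decay toward zero for the chosen option's value; the
`update_on_no_feedback` switch turns this off for users who prefer to
treat ambiguous outcomes as uninformative. All value tables start at
zero (the symmetric choice) and the choice-kernel indicator starts
all-zero.

The valence-split update applies the positive-error rate when δ > 0 and
the negative-error rate when δ < 0; δ = 0 moves nothing. Q-learning
uses a single rate for both signs. The actor-critic kinds compute δ
against the critic's stimulus value V(s) and convey the same δ to the
actor's preference for the chosen action; their choice rule reads the
actor preferences P, not Q. The perseveration weight φ appears in the
softmax of every kind but is fixed at 0 unless a "+kernel" variant
explicitly frees it, keeping the free-parameter counts of the
four-member family at 2/3/4/5.

With outcomes in [−1, 1], rates in [0, 1] and zero initialization, Q
and V are convex combinations of past outcomes and stay in [−1, 1];
actor preferences P accumulate and are unbounded, which is why the
boundedness invariant covers Q and V only.

## Fitting

Per-subject maximum likelihood: the session is replayed under teacher
forcing (state updated with the subject's actual responses and observed
feedback) and the objective is negLLE = −Σₜ log Pr(rₜ) over non-top-up
trials. Search bounds are [0, 1] for learning rates, [0, 20] for β
(wide enough that unit-coded values saturate the softmax), [−5, 5] for
φ when free. The optimizer runs L-BFGS-B from 10 (default) uniform
interior starts with ftol 1e−6; a non-converged restart is polished
with bounded Nelder–Mead, and the best restart wins. Because β = 0 is
inside the box, chance (n·ln 2) upper-bounds any fitted negLLE. Each
subject in a cohort fit receives an independently spawned RNG stream,
so results are reproducible and order-insensitive. Hierarchical
(shrinkage) estimation is out of scope; the `extra_starts` hook is the
extension point for warm-starting from group-level estimates.

## Model comparison

Two criteria are reported. The primary table uses
k·ln(n) − 2·ln(negLLE) evaluated at the cohort *mean* negLLE with
n = 160, displayed truncated (floored toward zero) to two decimals —
truncation, not rounding, is what the reference arithmetic is
consistent with. This criterion takes the log *of* the negLLE, so it
decreases as fit quality worsens; it is reproduced for comparability
and the conventional BIC = k·ln(n) + 2·negLLE is computed alongside and
used wherever a proper evidence approximation is needed. Random-effects
Bayesian model selection treats each subject's generating model as a
draw from a population Dirichlet: per-subject log evidence is
approximated by −BIC/2 (the standard Laplace-style choice for this
procedure), responsibilities and Dirichlet concentrations are iterated
to a 1e−6 fixed point, and exceedance probabilities are estimated from
Dirichlet draws (1e5 by default; sampling error ~1e−3). Expected
posterior probabilities sum to one by construction. Mean (not median)
negLLE is reported and labelled as such. Protected exceedance
probabilities and family-level comparison are not implemented.

## Synthetic cohorts

The generator exists to make the pipeline testable with a known ground
truth, not as a mechanistic claim about anxiety. Groups GAD (n = 18),
SAD (n = 20), PAD (n = 17) and HC (n = 18) — 73 agents — play full
sessions through the actual task runner. The generating model is
`actor_only` (3 parameters): the group effect is a valence asymmetry,
which that model expresses directly through its split learning rates,
while *fitting* demonstrations default to the 2-parameter Q-learning
model — deliberately simpler than the generator, mirroring the typical
outcome that parsimony selects Q-learning even when the behavior has
richer structure. Fitted Q-learning parameters on the default cohort
need not separate the groups even though behavior does: a single-rate
model cannot express the valence asymmetry, so the group signal lives
in the behavioral accuracy, not in α or β.

Calibration (frozen; `scripts/calibrate_cohort.py` re-runs the check):
all groups share αa⁺ ~ TruncNormal(0.40, 0.05) on [0, 1] and
β ~ TruncNormal(4.0, 0.3) on [0.5, 12]; αa⁻ is
TruncNormal(0.35, 0.06) for GAD/SAD and TruncNormal(0.12, 0.04) for
PAD/HC. The αa⁺ center sits at a crossover that makes the positive
condition insensitive to αa⁻: a higher αa⁻ both decays the common
action's value (hurting positive accuracy) and suppresses the rare
action's occasional-reward value (helping it), and at αa⁺ ≈ 0.4, β ≈ 4
the two effects cancel, so group positive-feedback rates differ only by
sampling noise. Under this calibration the block-4 negative-feedback
accuracy orders GAD ≈ SAD > PAD ≈ HC with a gap of roughly 0.05–0.10,
and positive-feedback accuracy (averaged across blocks, 80
trials/subject — the lower-variance reading of "matched") stays within
0.05 across groups for the large majority of seeds; with ~18 subjects
per group the four-group range occasionally exceeds 0.05 by chance
alone, which is consistent with real cohorts showing nonsignificant but
not identical group means. Demographic columns (age, education, HAM-A
anxiety severity) are sampled per group from plausible clinical means
and SDs purely as inert metadata.

What passing the cohort tests does *not* show: that real GAD/SAD
patients implement valence-split Q-learning, that the effect size
matches any particular clinical sample, or that fitted parameters would
separate diagnostic groups in real data. The generator omits
comorbidity, medication, attention lapses, response-time structure and
within-session nonstationarity of strategies.

## Behavioral metrics

Accuracy cells are (subject, block, valence) with 20 trials each under
the default design. Above-chance testing averages the four block
proportions within subject per valence and applies a two-sided
one-sample t-test against 0.5, reporting the Bonferroni-adjusted
α = 0.0125 for the four groups. Zero-variance cells are flagged
degenerate rather than producing a spurious finite t. Omnibus
mixed-design ANOVAs are deliberately not reimplemented: the tidy
accuracy table is the interface to any general statistics environment.

## Problem sizes and numerical choices

Parameter-recovery validation uses 100 agents × 160 trials with 5
restarts, and the model-selection demonstration uses cohorts of ~12–24
subjects with 4 restarts — sizes at which the relevant effects
(recovery correlation > 0.5, selection of the true generator) are
already unambiguous. The likelihood replay is an O(trials) scalar loop;
log-probabilities use `logaddexp` so extreme β values cannot overflow.
Optimizer ties between restarts resolve to the first-seen minimum;
truncation of displayed criteria happens only at the display layer, all
comparisons use full precision.
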