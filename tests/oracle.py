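"""Independent brute-force oracles used to cross-check the package.

Deliberately written against the model equations from first principles
(plain dicts, no shared code with valencerl's replay loop) so that
agreement between the two is evidence of correctness, not of shared
bugs.
"""

import math

import numpy as np


def oracle_neg_log_likelihood(kind_name, params, log, update_on_no_feedback=True):
    """Trial-by-trial teacher-forced replay of a session log.

    ``params`` is any object with alpha/alpha_a_plus/.../beta/phi
    attributes; ``log`` is a valencerl SessionLog (only TrialRecord
    fields are read). Returns -sum log Pr(subject's response).
    """
    uses_critic = kind_name.startswith("actor_critic")
    beta = 1.0 if kind_name == "actor_critic_no_beta" else params.beta
    phi = params.phi if kind_name.endswith("+kernel") else 0.0

    values = {}  # (stimulus, action) -> Q or actor preference
    critic = {}  # stimulus -> V
    last_choice = {}  # stimulus -> last action
    total = 0.0
    for t in log.trials:
        if t.topup:
            continue
        s = t.stimulus
        x_a = values.get((s, "A"), 0.0)
        x_b = values.get((s, "B"), 0.0)
        kernel = 0.0
        if s in last_choice:
            kernel = 1.0 if last_choice[s] == "A" else -1.0
        z = beta * (x_a - x_b) + phi * kernel
        p_a = 1.0 / (1.0 + math.exp(-z))
        p_resp = p_a if t.response == "A" else 1.0 - p_a
        total -= math.log(p_resp)

        o = float(np.sign(t.feedback_points))
        if update_on_no_feedback or o != 0.0:
            if uses_critic:
                delta = o - critic.get(s, 0.0)
                rate_c = params.alpha_c_plus if delta > 0 else params.alpha_c_minus
                critic[s] = critic.get(s, 0.0) + rate_c * delta
                rate_a = params.alpha_a_plus if delta > 0 else params.alpha_a_minus
                key = (s, t.response)
                values[key] = values.get(key, 0.0) + rate_a * delta
            else:
                key = (s, t.response)
                delta = o - values.get(key, 0.0)
                if kind_name.startswith("q_learning"):
                    rate = params.alpha
                else:
                    rate = params.alpha_a_plus if delta > 0 else params.alpha_a_minus
                values[key] = values.get(key, 0.0) + rate * delta
        last_choice[s] = t.response
    return total


def oracle_dirichlet_posterior_mean(log_evidence, prior_alpha=1.0,
                                    n_samples=200_000, seed=0):
    """Importance-sampling estimate of E[model frequencies | data].

    Model: r ~ Dirichlet(prior), each subject's model ~ Categorical(r),
    data likelihood per subject = sum_k r_k * exp(log_ev_nk). Draws r
    from the prior and weights by the marginal likelihood; feasible for
    small cohorts only.
    """
    ev = np.asarray(log_evidence, dtype=float)
    ev = ev - ev.max(axis=1, keepdims=True)  # per-subject scale cancels
    n_models = ev.shape[1]
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(np.full(n_models, float(prior_alpha)), size=n_samples)
    # log weight = sum_n log(sum_k r_k exp(ev_nk))
    logw = np.log(r @ np.exp(ev).T).sum(axis=1)
    logw -= logw.max()
    w = np.exp(logw)
    return (r * w[:, None]).sum(axis=0) / w.sum()
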