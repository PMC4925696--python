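"""Administer one task session to a hand-written agent.

Builds the four-stimulus task, lets an always-optimal responder play
the 160 trials, and prints the trial accounting and point tally.
"""

from valencerl import SessionConfig
from valencerl.task import anti_optimal_agent, optimal_agent, run_session

cfg = SessionConfig()
log = run_session(optimal_agent(), cfg, rng_seed=0, subject_id="demo")
print(f"main trials: {len(log.main_trials)}  final tally: {log.final_points}")

pessimal = run_session(anti_optimal_agent(), cfg, rng_seed=0)
n_topup = sum(t.topup for t in pessimal.trials)
print(f"pessimal agent: final tally {pessimal.final_points} "
      f"after {n_topup} top-up trials")

# The optimal responder banks +25 on 8/10 positive-valence trials and
# loses 25 on the 2/10 rare negative-valence trials (500 + 1600 - 400 =
# 1700). The pessimal agent ends deep below the 500-point floor, so
# forced-correct top-up trials lift it to the 525-point target.
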