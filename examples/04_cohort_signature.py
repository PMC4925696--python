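"""Generate the default synthetic clinical cohort and show its signature.

73 agents in four groups (GAD, SAD, PAD, HC) play the task. GAD/SAD
agents carry an elevated learning rate for negative prediction errors;
everything else is matched. The printout shows the behavioral
dissociation this produces: a group gap in negative-feedback accuracy
by block 4, none in positive-feedback accuracy, plus per-group
above-chance tests.
"""

from valencerl import accuracy_table, chance_test, generate_cohort, group_summary

cohort = generate_cohort(rng_seed=0)
table = accuracy_table(cohort.logs)

block4 = group_summary(table[table["block"] == 4])
print("block-4 mean proportion optimal (SEM):")
for _, row in block4.iterrows():
    print(f"  {row['group']:>3} {row['valence']:>8}: "
          f"{row['mean_proportion']:.3f} ({row['sem']:.3f})")

print("\nabove-chance tests (mean accuracy across blocks vs 0.5, "
      "Bonferroni alpha 0.0125):")
tests = chance_test(table)
for _, row in tests.iterrows():
    print(f"  {row['group']:>3} {row['valence']:>8}: t({row['df']})="
          f"{row['t']:.2f}  p={row['p']:.2e}")

# Negative-feedback accuracy at block 4 orders GAD ~ SAD > PAD ~ HC
# (the anxiety-subtype dissociation the generator encodes), while the
# positive-feedback columns sit within a few percent of each other;
# every group learns above chance in both conditions.
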