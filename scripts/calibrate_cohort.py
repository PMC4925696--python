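"""Calibration check for the synthetic-cohort generator defaults.

Simulates the default cohort across several seeds and prints the two
quantities the calibration must satisfy:

* block-4 negative-feedback optimal-response means ordered
  GAD ~ SAD > PAD ~ HC (the anxiety-subtype dissociation), and
* positive-feedback means within 0.05 of each other across groups.

The distribution constants in ``valencerl.cohort.default_group_specs``
were chosen once with this script and then frozen; rerun it after any
deliberate recalibration, not as part of routine testing.

Usage: python scripts/calibrate_cohort.py [n_seeds]
"""

import sys

import pandas as pd

from valencerl import accuracy_table, generate_cohort


def signature(seed: int) -> pd.DataFrame:
    cohort = generate_cohort(rng_seed=seed)
    table = accuracy_table(cohort.logs)
    b4 = table[table["block"] == 4]
    return (
        b4.groupby(["group", "valence"])["proportion_optimal"].mean().unstack()
    )


def main() -> None:
    n_seeds = int(sys.argv[1]) if len(sys.argv) > 1 else 5
    for seed in range(n_seeds):
        sig = signature(seed)
        neg = sig["negative"]
        pos = sig["positive"]
        ordered = min(neg["GAD"], neg["SAD"]) > max(neg["PAD"], neg["HC"])
        matched = pos.max() - pos.min() < 0.05
        print(f"seed {seed}: negative " +
              " ".join(f"{g}={neg[g]:.3f}" for g in ("GAD", "SAD", "PAD", "HC")) +
              f" | positive spread {pos.max() - pos.min():.3f}" +
              f" | ordered={ordered} matched={matched}")


if __name__ == "__main__":
    main()
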