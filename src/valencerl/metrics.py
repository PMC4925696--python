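"""Descriptive behavioral metrics: optimal-response accuracy and chance tests.

The behavioral surface of the task is the proportion of *optimal*
responses — choosing the stimulus's 80% category regardless of the
sampled outcome — broken down by block and feedback valence. Under the
default task each (subject, block, valence) cell holds 20 trials
(2 stimuli x 10 repetitions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .task import SessionLog

#: Bonferroni-adjusted alpha for the four per-group chance tests.
BONFERRONI_ALPHA = 0.0125


class DataError(ValueError):
    pass


def accuracy_table(session_logs: list[SessionLog]) -> pd.DataFrame:
    """Optimal-response counts per (subject, block, valence) cell.

    Top-up trials are excluded. Columns: subject_id, group, block,
    valence, n_trials, n_optimal, proportion_optimal.
    """
    frames = []
    for log in session_logs:
        frame = log.to_frame()
        if frame.empty:
            raise DataError(f"subject {log.subject_id}: empty log")
        frames.append(frame[~frame["topup"]])
    trials = pd.concat(frames, ignore_index=True)
    bad = trials[~trials["response"].isin(["A", "B"])]
    if not bad.empty:
        raise DataError(f"invalid responses in rows {bad.index.tolist()[:5]}")
    grouped = (
        trials.groupby(["subject_id", "group", "block", "valence"], sort=True)
        .agg(n_trials=("optimal", "size"), n_optimal=("optimal", "sum"))
        .reset_index()
    )
    grouped["proportion_optimal"] = grouped["n_optimal"] / grouped["n_trials"]
    return grouped


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of proportion_optimal per (group, block, valence).

    SEM uses the sample standard deviation (ddof=1) over subjects; a
    single-subject cell reports SEM 0 by convention.
    """
    if table.empty:
        raise DataError("empty accuracy table")

    def _sem(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1) / np.sqrt(len(x)))

    out = (
        table.groupby(["group", "block", "valence"], sort=True)["proportion_optimal"]
        .agg(mean_proportion="mean", sem=_sem, n_subjects="size")
        .reset_index()
    )
    return out


def subject_mean_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean of the block proportions, per valence."""
    return (
        table.groupby(["subject_id", "group", "valence"], sort=True)[
            "proportion_optimal"
        ]
        .mean()
        .rename("mean_accuracy")
        .reset_index()
    )


def chance_test(table: pd.DataFrame, null: float = 0.5) -> pd.DataFrame:
    """One-sample t-test of mean accuracy against chance, per group x valence.

    Accuracy is first averaged across blocks within subject, then tested
    against ``null`` with a two-sided one-sample t-test. The
    Bonferroni-adjusted alpha across the four groups (0.0125) is
    reported alongside. Zero-variance cells off the null are flagged
    degenerate (infinite t).
    """
    per_subj = subject_mean_accuracy(table)
    rows = []
    for (grp, val), sub in per_subj.groupby(["group", "valence"], sort=True):
        x = sub["mean_accuracy"].to_numpy()
        if len(x) < 2:
            raise DataError(f"group {grp}/{val}: need >= 2 subjects for a t-test")
        degenerate = bool(np.isclose(x.std(ddof=1), 0.0))
        if degenerate:
            t = 0.0 if np.isclose(x.mean(), null) else np.inf * np.sign(x.mean() - null)
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_1samp(x, null)
        rows.append(
            {
                "group": grp,
                "valence": val,
                "n": len(x),
                "mean_accuracy": float(x.mean()),
                "t": float(t),
                "df": len(x) - 1,
                "p": float(p),
                "alpha_bonferroni": BONFERRONI_ALPHA,
                "significant": bool(float(p) < BONFERRONI_ALPHA),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def plot_learning_curves(summary: pd.DataFrame, ax_pair=None):
    """Figure-style learning curves: mean optimal proportion (+SEM) per
    block, one panel per valence, one line per group. Requires
    matplotlib; returns the two axes."""
    import matplotlib.pyplot as plt

    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, valence in zip(ax_pair, ("positive", "negative")):
        sub = summary[summary["valence"] == valence]
        for grp, g in sub.groupby("group"):
            ax.errorbar(g["block"], g["mean_proportion"], yerr=g["sem"],
                        marker="o", capsize=2, label=grp)
        ax.axhline(0.5, color="gray", lw=0.8, ls="--")
        ax.set_title(f"{valence} feedback")
        ax.set_xlabel("block")
        ax.set_xticks(sorted(sub["block"].unique()))
    ax_pair[0].set_ylabel("proportion optimal")
    ax_pair[0].legend(fontsize=8)
    return ax_pair
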