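"""Traditional (model-free) analyses of go/no-go task behaviour.

Condition accuracies, Pavlovian bias indices, the congruent-vs-incongruent
paired contrast, the 2x2 (action x valence) repeated-measures ANOVA, binned
learning curves, reaction-time summaries and paired effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import GO, MISSED, NOGO, Condition

DEADLINE = 1.5  # response deadline, seconds

_CORRECT = {c.name: c.correct_action for c in Condition}
_CONGRUENT = {c.name: c.congruent for c in Condition}
_VALENCE = {c.name: c.valence for c in Condition}


def _effective_action(actions: pd.Series) -> pd.Series:
    # a missed response counts as a no-go for accuracy purposes
    return actions.replace({MISSED: NOGO})


def accuracy_by_condition(data: pd.DataFrame) -> pd.DataFrame:
    """Per subject x administration x condition: accuracy, mean go RT, miss rate.

    Accuracy is the fraction of trials whose (effective) action matches the
    condition's correct action.  Condition cells with no trials are simply
    absent from the output rather than reported as zero.
    """
    df = data.copy()
    df["effective_action"] = _effective_action(df["action"])
    df["correct"] = df["effective_action"] == df["condition"].map(_CORRECT)
    df["missed"] = df["action"] == MISSED
    has_rt = "rt" in df.columns
    go_rt = df["rt"].where(df["effective_action"] == GO) if has_rt else np.nan

    grouped = df.assign(go_rt=go_rt).groupby(
        ["subject_id", "administration", "condition"], sort=True
    )
    out = grouped.agg(
        n_trials=("correct", "size"),
        accuracy=("correct", "mean"),
        mean_rt=("go_rt", "mean"),
        missed_rate=("missed", "mean"),
    ).reset_index()
    return out


def pavlovian_bias_index(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Pavlovian bias indices.

    appetitive bias = acc(GO_WIN) - acc(NOGO_WIN);
    aversive bias = acc(NOGO_AVOID) - acc(GO_AVOID).  A missing condition
    cell leaves the corresponding index absent (NaN).
    """
    acc = summary.groupby(["subject_id", "condition"])["accuracy"].mean().unstack("condition")
    for name in _CORRECT:
        if name not in acc.columns:
            acc[name] = np.nan
    out = pd.DataFrame(
        {
            "appetitive_bias": acc["GO_WIN"] - acc["NOGO_WIN"],
            "aversive_bias": acc["NOGO_AVOID"] - acc["GO_AVOID"],
        }
    ).reset_index()
    return out


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def congruency_ttest(summary: pd.DataFrame) -> PairedTestResult:
    """Paired t test of congruent vs incongruent accuracy across subjects."""
    df = summary.copy()
    df["congruent"] = df["condition"].map(_CONGRUENT)
    means = df.groupby(["subject_id", "congruent"])["accuracy"].mean().unstack("congruent")
    means = means.dropna()
    if len(means) < 3:
        raise ValueError("congruency_ttest needs at least 3 subjects with both means")
    diffs = means[True] - means[False]
    n = len(diffs)
    if np.isclose(diffs.std(ddof=1), 0.0):
        return PairedTestResult(t=np.nan, df=n - 1, p=np.nan, degenerate=True)
    t, p = stats.ttest_rel(means[True], means[False])
    return PairedTestResult(t=float(t), df=n - 1, p=float(p))


def rm_anova_2x2(summary: pd.DataFrame) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA of accuracy on action x valence.

    Cell means are computed per subject; subjects with incomplete 2x2 cells
    are excluded.  With 1-df factors every F equals the square of the paired
    t on the corresponding marginal means, which is asserted in-op.
    """
    df = summary.copy()
    df["action_factor"] = df["condition"].map(_CORRECT)
    df["valence"] = df["condition"].map(_VALENCE)
    cells = (
        df.groupby(["subject_id", "action_factor", "valence"])["accuracy"]
        .mean()
        .unstack(["action_factor", "valence"])
    )
    complete = cells.dropna()
    dropped = set(cells.index) - set(complete.index)
    if dropped:
        import warnings

        warnings.warn(f"subjects excluded for incomplete cells: {sorted(dropped)}", stacklevel=2)
    if len(complete) < 2:
        raise ValueError("rm_anova_2x2 needs >= 2 subjects with complete cells")
    y = complete.to_numpy()  # n x 4, columns (go,win) (go,loss) (nogo,win) (nogo,loss)
    cols = list(complete.columns)
    a = np.array([1.0 if c[0] == GO else -1.0 for c in cols])
    v = np.array([1.0 if c[1] == "win" else -1.0 for c in cols])
    rows = []
    for effect, contrast in (("action", a), ("valence", v), ("action x valence", a * v)):
        scores = y @ contrast / 2.0  # per-subject contrast on cell means
        n = scores.size
        mean = scores.mean()
        se = scores.std(ddof=1) / np.sqrt(n)
        t = mean / se if se > 0 else np.nan
        F = t**2 if np.isfinite(t) else np.nan
        p = stats.f.sf(F, 1, n - 1) if np.isfinite(F) else np.nan
        # 1-df identity check against the direct paired t on marginals
        pos = y[:, contrast > 0].mean(axis=1)
        neg = y[:, contrast < 0].mean(axis=1)
        if np.isfinite(t):
            t_check = stats.ttest_rel(pos, neg)[0]
            assert abs(F - t_check**2) < 1e-10 * max(1.0, F)
        rows.append({"effect": effect, "F": F, "df1": 1, "df2": n - 1, "p": p})
    return pd.DataFrame(rows)


def binned_learning_curves(data: pd.DataFrame, bin_size: int = 10) -> pd.DataFrame:
    """Go-rate per subject x administration x condition x trial bin.

    Trial position is counted within condition (per administration); the
    trailing partial bin is retained and flagged ``partial``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = data.copy()
    df["go"] = (_effective_action(df["action"]) == GO).astype(float)
    df = df.sort_values(["subject_id", "administration", "trial_index"])
    df["position"] = df.groupby(["subject_id", "administration", "condition"]).cumcount() + 1
    df["bin"] = (df["position"] - 1) // bin_size
    out = (
        df.groupby(["subject_id", "administration", "condition", "bin"])
        .agg(n_trials=("go", "size"), go_rate=("go", "mean"))
        .reset_index()
    )
    out["partial"] = out["n_trials"] < bin_size
    return out


def rt_summary(data: pd.DataFrame, deadline: float = DEADLINE) -> pd.DataFrame:
    """Per-subject mean go reaction time and deadline-miss proportion.

    The miss proportion counts trials flagged ``missed`` as well as button
    presses slower than the deadline; the mean RT averages go responses
    within the deadline.  Subjects without any recorded RT are flagged
    unavailable.
    """
    df = data.copy()
    has_rt = df["rt"].notna()
    go_mask = df["action"] == GO
    timely = go_mask & has_rt & (df["rt"] <= deadline)
    late = (df["action"] == MISSED) | (go_mask & has_rt & (df["rt"] > deadline))
    out = (
        pd.DataFrame(
            {
                "subject_id": df["subject_id"],
                "timely_rt": df["rt"].where(timely),
                "late": late.astype(float),
                "any_rt": (has_rt | (df["action"] == MISSED)).astype(float),
            }
        )
        .groupby("subject_id")
        .agg(mean_go_rt=("timely_rt", "mean"), miss_proportion=("late", "mean"), n_rt=("any_rt", "sum"))
        .reset_index()
    )
    out["available"] = out["n_rt"] > 0
    out.loc[~out["available"], ["mean_go_rt", "miss_proportion"]] = np.nan
    return out.drop(columns="n_rt")


@dataclass
class EffectSize:
    d_change: float
    d_pooled: float
    degenerate: bool = False


def cohens_d_change(pre, post) -> EffectSize:
    """Paired effect size of a pre-to-post change, under both common conventions.

    ``d_change`` divides the mean change by the SD of the change scores;
    ``d_pooled`` divides by the root-mean of the two cross-sectional
    variances.  Both are reported because the convention is frequently left
    implicit in clinical reports.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre and post must be paired vectors of length >= 2")
    change = pre - post
    sd_change = change.std(ddof=1)
    pooled = np.sqrt((pre.var(ddof=1) + post.var(ddof=1)) / 2.0)
    if np.isclose(sd_change, 0.0):
        return EffectSize(d_change=np.nan, d_pooled=np.nan, degenerate=True)
    return EffectSize(
        d_change=float(change.mean() / sd_change),
        d_pooled=float(change.mean() / pooled) if pooled > 0 else np.nan,
    )
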