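"""Subject-level summaries, group descriptive tables, and a permutation test
for group-by-condition interactions.

Per subject and masker condition the pipeline reports: keyword accuracy, the
proportion of sentences classified DNH-Nothing and DNH-Incorrect (out of all
sentences presented in that condition), and the mean number of content-word,
function-word, and morpheme errors per sentence computed over the non-DNH
sentences only (substitutions, additions, and omissions pooled within each
word class).  Masker overlap is pooled across a subject's DNH-Incorrect
single-talker trials.

Group inference here is deliberately design-based: a permutation test of the
group-by-condition interaction (difference of group differences between a
focal condition and the mean of the remaining conditions), with subject
group labels permuted.  Mixed-effects modeling of the same summaries is
standard and can be applied downstream to the exported per-subject table;
the permutation test keeps the package self-contained and assumption-light.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import (DNH_INCORRECT, DNH_NONE, DNH_NOTHING, TrialScore)

__all__ = [
    "SubjectConditionSummary", "METRICS",
    "summarize_subject", "masker_overlap_summary",
    "summaries_frame", "group_table", "permutation_interaction_test",
]

#: The six per-subject analysis metrics.
METRICS = ("keyword_accuracy", "p_dnh_nothing", "p_dnh_incorrect",
           "mean_content_errors", "mean_function_errors", "mean_morpheme_errors")


@dataclass(frozen=True)
class SubjectConditionSummary:
    subject_id: str
    group: str
    condition: str
    keyword_accuracy: float
    p_dnh_nothing: float
    p_dnh_incorrect: float
    mean_content_errors: float   # NaN when every trial is DNH
    mean_function_errors: float
    mean_morpheme_errors: float
    masker_overlap: float        # NaN unless 1T with DNH-Incorrect trials
    n_trials: int
    n_non_dnh: int


def summarize_subject(subject_id: str, group: str, condition: str,
                      scores: Sequence[TrialScore]) -> SubjectConditionSummary:
    """Aggregate one subject's trials in one condition.

    DNH proportions are over all trials; per-sentence error means are over
    the non-DNH trials only and are NaN (flagged missing) when no trial
    survives.  Raises ValueError on empty input.
    """
    if not scores:
        raise ValueError("summarize_subject requires at least one trial")
    n = len(scores)
    n_nothing = sum(1 for s in scores if s.dnh_status == DNH_NOTHING)
    n_incorrect = sum(1 for s in scores if s.dnh_status == DNH_INCORRECT)
    non_dnh = [s for s in scores if s.dnh_status == DNH_NONE]

    kw_flags = [b for s in scores for b in s.keyword_correct]
    kw_acc = sum(kw_flags) / len(kw_flags) if kw_flags else math.nan

    if non_dnh:
        mean_content = sum(s.content_errors.total for s in non_dnh) / len(non_dnh)
        mean_function = sum(s.function_errors.total for s in non_dnh) / len(non_dnh)
        mean_morph = sum(s.morpheme_errors for s in non_dnh) / len(non_dnh)
    else:
        mean_content = mean_function = mean_morph = math.nan

    overlap = masker_overlap_summary(scores) if condition == "1T" else math.nan

    return SubjectConditionSummary(
        subject_id=subject_id, group=group, condition=condition,
        keyword_accuracy=kw_acc,
        p_dnh_nothing=n_nothing / n, p_dnh_incorrect=n_incorrect / n,
        mean_content_errors=mean_content, mean_function_errors=mean_function,
        mean_morpheme_errors=mean_morph,
        masker_overlap=overlap, n_trials=n, n_non_dnh=len(non_dnh))


def masker_overlap_summary(scores: Sequence[TrialScore]) -> float:
    """Pooled proportion of DNH-Incorrect response content words found in the masker.

    Matched and total counts are pooled across the subject's DNH-Incorrect
    trials; NaN when the subject has none.
    """
    matched = total = 0
    for s in scores:
        if s.masker_overlap is not None:
            matched += s.masker_overlap[0]
            total += s.masker_overlap[1]
    return matched / total if total else math.nan


def summaries_frame(summaries: Sequence[SubjectConditionSummary]) -> pd.DataFrame:
    """One row per subject-by-condition summary."""
    return pd.DataFrame([vars(s) for s in summaries])


def group_table(summaries: pd.DataFrame | Sequence[SubjectConditionSummary],
                metrics: Sequence[str] = METRICS) -> pd.DataFrame:
    """Mean and sample SD (n-1) of each metric per group-by-condition cell.

    Cells with a single subject report the mean with SD missing; empty cells
    are simply absent.  Means average the per-subject summaries (each
    subject contributes equally, regardless of trial counts).
    """
    df = summaries_frame(summaries) if not isinstance(summaries, pd.DataFrame) else summaries
    out = df.groupby(["group", "condition"], sort=True)[list(metrics)] \
            .agg(["mean", "std", "count"])
    out.columns = [f"{m}_{stat}" for m, stat in out.columns]
    return out.reset_index()


def permutation_interaction_test(summaries: pd.DataFrame | Sequence[SubjectConditionSummary],
                                 metric: str, n_perm: int = 10_000,
                                 seed: int | None = None,
                                 focal_condition: str = "1T") -> dict:
    """Permutation test of a group-by-condition interaction on one metric.

    The observed statistic is the difference of group differences between
    the focal condition and the mean of the remaining conditions::

        stat = (mean_A - mean_B)[focal] - mean over other c of (mean_A - mean_B)[c]

    The null distribution permutes subject group labels (each subject keeps
    its full condition profile).  The two-sided p-value uses the add-one
    estimator p = (1 + #{|null| >= |observed|}) / (1 + n_perm), which can
    never be exactly zero.  Subjects with a missing metric in any condition
    are dropped.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = summaries_frame(summaries) if not isinstance(summaries, pd.DataFrame) else summaries
    if metric not in df.columns:
        raise ValueError(f"unknown metric {metric!r}")

    wide = df.pivot(index="subject_id", columns="condition", values=metric)
    if focal_condition not in wide.columns:
        raise ValueError(f"focal condition {focal_condition!r} not present")
    groups = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
    wide = wide.dropna()
    groups = groups.loc[wide.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    others = [c for c in wide.columns if c != focal_condition]
    if not others:
        raise ValueError("need at least two conditions")

    # contrast vector over conditions: focal minus mean of the others
    cols = [focal_condition] + others
    M = wide[cols].to_numpy()
    contrast = np.array([1.0] + [-1.0 / len(others)] * len(others))
    per_subject = M @ contrast                     # focal-vs-rest per subject
    is_a = (groups.to_numpy() == labels[0])
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    observed = per_subject[is_a].mean() - per_subject[~is_a].mean()
    rng = np.random.default_rng(seed)
    # permuting the subject values is equivalent to permuting group labels
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(per_subject)
        null[k] = perm[:n_a].mean() - perm[n_a:].mean()
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (1 + n_perm)
    return {"metric": metric, "statistic": float(observed), "p": float(p),
            "n_perm": int(n_perm), "seed": seed,
            "focal_condition": focal_condition,
            "n_subjects": int(per_subject.size)}
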