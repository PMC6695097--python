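"""Glue between per-trial scores and the subject/group analyses."""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import pandas as pd

from .aggregate import (METRICS, SubjectConditionSummary, permutation_interaction_test,
                        summaries_frame, summarize_subject)
from .scoring import TrialRecord, TrialScore

__all__ = ["summarize_records", "run_interaction_tests"]


def summarize_records(records: Sequence[tuple[TrialRecord, TrialScore]]
                      ) -> list[SubjectConditionSummary]:
    """Per subject-by-condition summaries from scored trials (input order
    within a cell is irrelevant)."""
    cells: dict[tuple[str, str, str], list[TrialScore]] = defaultdict(list)
    for trial, score in records:
        cells[(trial.subject_id, trial.group, trial.condition)].append(score)
    return [summarize_subject(sid, grp, cond, scores)
            for (sid, grp, cond), scores in sorted(cells.items())]


def run_interaction_tests(summaries: Sequence[SubjectConditionSummary] | pd.DataFrame,
                          metrics: Sequence[str] = METRICS,
                          n_perm: int = 10_000, seed: int = 0,
                          focal_condition: str = "1T") -> list[dict]:
    """Permutation interaction test for each metric, with per-metric seeds
    derived deterministically from *seed*."""
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    results = []
    for k, metric in enumerate(metrics):
        results.append(permutation_interaction_test(
            df, metric, n_perm=n_perm, seed=seed + k,
            focal_condition=focal_condition))
    return results
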