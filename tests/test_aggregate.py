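"""Subject summaries, group tables, and the permutation interaction test."""

import math

import numpy as np
import pandas as pd
import pytest

import spinscore as sp
from spinscore.scoring import ErrorCounts, TrialScore


def make_score(dnh="none", content=(0, 0, 0), function=(0, 0, 0), morph=0,
               keywords=(True, True, True), overlap=None):
    if dnh != "none":
        return TrialScore(keyword_correct=keywords, dnh_status=dnh,
                          masker_overlap=overlap,
                          n_target_content=3, n_target_function=2)
    return TrialScore(keyword_correct=keywords, dnh_status=dnh,
                      content_errors=ErrorCounts(*content),
                      function_errors=ErrorCounts(*function),
                      morpheme_errors=morph,
                      n_target_content=3, n_target_function=2)


class TestSummarizeSubject:
    def test_dnh_proportions_over_all_trials(self):
        scores = [make_score("dnh_nothing")] * 2 + [make_score()] * 14
        s = sp.summarize_subject("s1", "MDD", "1T", scores)
        assert s.p_dnh_nothing == pytest.approx(2 / 16)
        assert s.p_dnh_incorrect == 0.0
        assert s.n_non_dnh == 14

    def test_error_means_over_non_dnh_only(self):
        scores = ([make_score("dnh_incorrect")]
                  + [make_score(content=(c, 0, 0)) for c in (0, 1, 2)])
        s = sp.summarize_subject("s1", "MDD", "1T", scores)
        assert s.mean_content_errors == pytest.approx(1.0)
        assert s.n_trials == 4 and s.n_non_dnh == 3

    def test_function_errors_pool_three_types(self):
        scores = [make_score(function=(1, 0, 0))] * 16
        s = sp.summarize_subject("s1", "control", "SSN", scores)
        assert s.mean_function_errors == pytest.approx(1.0)

    def test_all_dnh_flags_means_missing(self):
        scores = [make_score("dnh_nothing", keywords=(False,) * 3)] * 4
        s = sp.summarize_subject("s1", "MDD", "SSN", scores)
        assert math.isnan(s.mean_content_errors)
        assert s.p_dnh_nothing == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sp.summarize_subject("s1", "MDD", "1T", [])

    def test_trial_order_irrelevant(self):
        scores = [make_score(content=(1, 0, 0)), make_score("dnh_nothing"),
                  make_score(morph=2, keywords=(False, True, True))]
        a = sp.summarize_subject("s1", "MDD", "1T", scores)
        b = sp.summarize_subject("s1", "MDD", "1T", scores[::-1])
        assert a == b


class TestMaskerOverlapSummary:
    def test_pooled_across_trials(self):
        scores = [make_score("dnh_incorrect", overlap=(2, 2)),
                  make_score("dnh_incorrect", overlap=(1, 2))]
        assert sp.masker_overlap_summary(scores) == pytest.approx(0.75)

    def test_single_trial(self):
        assert sp.masker_overlap_summary(
            [make_score("dnh_incorrect", overlap=(0, 1))]) == 0.0

    def test_missing_when_no_dnh_incorrect(self):
        assert math.isnan(sp.masker_overlap_summary([make_score()]))


def summary(sid, group, cond, acc, **kw):
    base = dict(keyword_accuracy=acc, p_dnh_nothing=0.0, p_dnh_incorrect=0.0,
                mean_content_errors=0.0, mean_function_errors=0.0,
                mean_morpheme_errors=0.0, masker_overlap=math.nan,
                n_trials=16, n_non_dnh=16)
    base.update(kw)
    return sp.SubjectConditionSummary(subject_id=sid, group=group,
                                      condition=cond, **base)


class TestGroupTable:
    def test_mean_and_sample_sd(self):
        rows = [summary("a", "MDD", "1T", 0.6), summary("b", "MDD", "1T", 0.8)]
        gt = sp.group_table(rows, metrics=["keyword_accuracy"])
        assert gt["keyword_accuracy_mean"].iloc[0] == pytest.approx(0.7)
        assert gt["keyword_accuracy_std"].iloc[0] == pytest.approx(0.141421, abs=1e-5)

    def test_single_subject_cell_has_missing_sd(self):
        gt = sp.group_table([summary("a", "MDD", "1T", 0.6)],
                            metrics=["keyword_accuracy"])
        assert math.isnan(gt["keyword_accuracy_std"].iloc[0])

    def test_identical_subjects_sd_zero(self):
        rows = [summary(s, "control", "SSN", 0.5) for s in "abc"]
        gt = sp.group_table(rows, metrics=["keyword_accuracy"])
        assert gt["keyword_accuracy_std"].iloc[0] == 0.0

    def test_subjects_weighted_equally_not_by_trials(self):
        rows = [summary("a", "MDD", "1T", 1.0, n_trials=32),
                summary("b", "MDD", "1T", 0.0, n_trials=16)]
        gt = sp.group_table(rows, metrics=["keyword_accuracy"])
        assert gt["keyword_accuracy_mean"].iloc[0] == pytest.approx(0.5)


def two_group_summaries(rng, effect_1t=0.0, n=12):
    rows = []
    for g, base in (("MDD", 0.5), ("control", 0.5)):
        for i in range(n):
            sid = f"{g}{i}"
            bump = effect_1t if g == "MDD" else 0.0
            for cond in ("1T", "1T_tr", "SSN"):
                val = base + (bump if cond == "1T" else 0.0) + rng.normal(0, 0.05)
                rows.append(summary(sid, g, cond, float(np.clip(val, 0, 1))))
    return rows


class TestPermutationInteractionTest:
    def test_no_effect_gives_large_p(self):
        rng = np.random.default_rng(0)
        res = sp.permutation_interaction_test(
            sp.summaries_frame(two_group_summaries(rng)),
            "keyword_accuracy", n_perm=999, seed=1)
        assert res["p"] > 0.05

    def test_planted_focal_deficit_detected(self):
        rng = np.random.default_rng(0)
        res = sp.permutation_interaction_test(
            sp.summaries_frame(two_group_summaries(rng, effect_1t=0.10, n=20)),
            "keyword_accuracy", n_perm=999, seed=1)
        assert res["p"] < 0.05

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(2)
        df = sp.summaries_frame(two_group_summaries(rng))
        a = sp.permutation_interaction_test(df, "keyword_accuracy", 500, seed=9)
        b = sp.permutation_interaction_test(df, "keyword_accuracy", 500, seed=9)
        assert a["p"] == b["p"] and a["statistic"] == b["statistic"]

    def test_monte_carlo_stability_across_seeds(self):
        rng = np.random.default_rng(3)
        df = sp.summaries_frame(two_group_summaries(rng, effect_1t=0.3, n=20))
        ps = [sp.permutation_interaction_test(df, "keyword_accuracy",
                                              10_000, seed=s)["p"]
              for s in (1, 2)]
        assert abs(ps[0] - ps[1]) < 2 / 10_000

    def test_add_one_estimator_never_zero(self):
        rng = np.random.default_rng(4)
        df = sp.summaries_frame(two_group_summaries(rng, effect_1t=0.5, n=10))
        res = sp.permutation_interaction_test(df, "keyword_accuracy", 99, seed=0)
        assert res["p"] >= 1 / 100

    def test_invalid_arguments(self):
        rng = np.random.default_rng(5)
        df = sp.summaries_frame(two_group_summaries(rng))
        with pytest.raises(ValueError):
            sp.permutation_interaction_test(df, "keyword_accuracy", n_perm=0)
        with pytest.raises(ValueError):
            sp.permutation_interaction_test(df, "no_such_metric", n_perm=10)
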