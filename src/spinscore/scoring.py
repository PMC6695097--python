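"""Per-trial scoring: keyword accuracy, DNH classification, masker overlap,
and word- / morpheme-level error counts.

Each trial runs through a fixed pipeline:

1. tokenize and tag the target and response, marking target keywords;
2. correct out-of-vocabulary response words that misspell a target content
   word;
3. score the designated keywords (exact form required — a keyword with any
   morpheme added or deleted is wrong);
4. classify whole-sentence omissions ("Did Not Hear"): if no response
   content word shares a *root* with any target content word (forms of "to
   be" never count as content), the trial is DNH — *DNH-Nothing* when the
   response has no content words at all, *DNH-Incorrect* when it has content
   words but none from the target.  DNH trials are excluded from word- and
   morpheme-level scoring; DNH-Incorrect responses in the intelligible
   single-talker condition are additionally compared against the masker
   sentence inventory to measure masker intrusion;
5. otherwise, align the sentences and count word-level errors (substitution,
   addition, omission, split by content vs function class) and
   morpheme-level errors (aligned content words that differ in surface form
   but share a root, e.g. pluralization or tense change).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import (Alignment, DEFAULT_WEIGHTS, WeightConfig, align,
                        MATCH, PARTIAL, MISMATCH, TARGET_GAP, RESPONSE_GAP)
from .lexicon import Lexicon, Token, correct_spelling, tag_sentence

__all__ = [
    "GROUPS", "CONDITIONS", "DNH_NONE", "DNH_NOTHING", "DNH_INCORRECT",
    "TrialRecord", "ErrorCounts", "TrialScore",
    "score_keywords", "classify_dnh", "masker_overlap",
    "score_word_errors", "score_morpheme_errors", "score_trial", "score_trials",
]

GROUPS = ("MDD", "control")
CONDITIONS = ("1T", "1T_tr", "SSN")

DNH_NONE = "none"
DNH_NOTHING = "dnh_nothing"
DNH_INCORRECT = "dnh_incorrect"


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation: who heard what and what they typed."""

    subject_id: str
    group: str
    condition: str
    target: str            # target sentence; keywords in UPPERCASE
    response: str          # typed response, possibly empty
    masker_id: str | None = None  # reference into the masker inventory (1T only)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class ErrorCounts:
    substitution: int = 0
    addition: int = 0
    omission: int = 0

    @property
    def total(self) -> int:
        return self.substitution + self.addition + self.omission


@dataclass(frozen=True)
class TrialScore:
    """All per-trial outcomes.

    Word- and morpheme-level counts are None for DNH trials (they are
    excluded from those analyses); ``masker_overlap`` is (matched, total)
    content-word counts and present only for DNH-Incorrect trials in the
    single-talker condition.
    """

    keyword_correct: tuple[bool, ...]
    dnh_status: str
    masker_overlap: tuple[int, int] | None = None
    content_errors: ErrorCounts | None = None
    function_errors: ErrorCounts | None = None
    morpheme_errors: int | None = None
    alignment: Alignment | None = None
    n_target_content: int = 0
    n_target_function: int = 0

    @property
    def keyword_accuracy(self) -> float | None:
        if not self.keyword_correct:
            return None
        return sum(self.keyword_correct) / len(self.keyword_correct)


def score_keywords(target: Sequence[Token], response: Sequence[Token]) -> tuple[bool, ...]:
    """Exact-form keyword scoring: one boolean per keyword token, in order.

    A keyword is correct iff its normalized form appears among the response
    words, position-independent; each response word can satisfy at most one
    keyword, and morphological variants never count.
    """
    available = Counter(r.norm for r in response)
    out = []
    for t in target:
        if not t.is_keyword:
            continue
        if available[t.norm] > 0:
            available[t.norm] -= 1
            out.append(True)
        else:
            out.append(False)
    return tuple(out)


def classify_dnh(target: Sequence[Token], response: Sequence[Token]) -> str:
    """Whole-sentence omission status, decided at the root level.

    Forms of "to be" are not content words here.  If any response content
    word's root matches a target content root the trial is not DNH;
    otherwise it is DNH-Nothing (no content transcribed at all) or
    DNH-Incorrect (only off-target content transcribed).
    """
    target_roots = {t.root for t in target if t.cls == "content"}
    response_content = [r for r in response if r.cls == "content"]
    if any(r.root in target_roots for r in response_content):
        return DNH_NONE
    return DNH_NOTHING if not response_content else DNH_INCORRECT


def masker_overlap(response: Sequence[Token], masker_roots: frozenset[str] | set[str],
                   *, match_level: str = "root") -> tuple[int, int]:
    """(matched, total) content words of a DNH-Incorrect response found in the masker.

    ``match_level`` selects whether response content words are compared to
    the masker inventory by root (default) or surface form.
    """
    content = [r for r in response if r.cls == "content"]
    if match_level == "root":
        matched = sum(1 for r in content if r.root in masker_roots)
    elif match_level == "surface":
        matched = sum(1 for r in content if r.norm in masker_roots)
    else:
        raise ValueError(f"unknown match level {match_level!r}")
    return matched, len(content)


def _is_function_like(tok: Token) -> bool:
    # be-forms are scored with function words
    return tok.cls in ("function", "be_form")


def score_word_errors(alignment: Alignment) -> tuple[ErrorCounts, ErrorCounts]:
    """Count substitutions, additions, and omissions of content and function words.

    Additions (response word against a target gap) are attributed to the
    response word's class; omissions (target word against a response gap) to
    the target word's class.  A paired mismatch of two function words counts
    as a function substitution whenever the words are not identical; a
    paired mismatch of two content words counts as a content substitution
    only when their roots also differ (same-root pairs are morpheme errors,
    not substitutions).  A cross-class pairing is a substitution attributed
    to the target word's class.
    """
    content: Counter = Counter()
    function: Counter = Counter()

    for p in alignment.pairs:
        if p.kind == TARGET_GAP:
            bucket = function if _is_function_like(p.response) else content
            bucket["addition"] += 1
        elif p.kind == RESPONSE_GAP:
            bucket = function if _is_function_like(p.target) else content
            bucket["omission"] += 1
        elif p.kind in (PARTIAL, MISMATCH):
            t, r = p.target, p.response
            t_fn, r_fn = _is_function_like(t), _is_function_like(r)
            if t_fn and r_fn:
                function["substitution"] += 1
            elif not t_fn and not r_fn:
                if t.root != r.root:
                    content["substitution"] += 1
                # same root -> morpheme error, handled by score_morpheme_errors
            else:
                bucket = function if t_fn else content
                bucket["substitution"] += 1

    return (ErrorCounts(content["substitution"], content["addition"], content["omission"]),
            ErrorCounts(function["substitution"], function["addition"], function["omission"]))


def score_morpheme_errors(alignment: Alignment) -> int:
    """Count aligned content-word pairs that differ in form but share a root."""
    n = 0
    for p in alignment.pairs:
        if p.kind in (PARTIAL, MISMATCH):
            t, r = p.target, p.response
            if t.cls == "content" and r.cls == "content" and t.norm != r.norm \
                    and t.root == r.root:
                n += 1
    return n


def score_trial(trial: TrialRecord, lexicon: Lexicon,
                weights: WeightConfig = DEFAULT_WEIGHTS,
                masker_roots: frozenset[str] | set[str] | None = None,
                *, masker_match_level: str = "root",
                keyword_norms: Iterable[str] | None = None,
                keep_alignment: bool = True) -> TrialScore:
    """Run the full scoring pipeline for one trial.

    ``masker_roots`` is the content-word root inventory of the competing
    talker's sentences; it is consulted only for DNH-Incorrect trials in the
    1T condition.
    """
    target = tag_sentence(trial.target, lexicon, keyword_norms)
    response = tag_sentence(trial.response, lexicon)
    response = correct_spelling(response, target, lexicon)

    keyword_correct = score_keywords(target, response)
    dnh = classify_dnh(target, response)

    n_content = sum(1 for t in target if t.cls == "content")
    n_function = len(target) - n_content

    overlap = None
    if dnh == DNH_INCORRECT and trial.condition == "1T" and masker_roots is not None:
        overlap = masker_overlap(response, masker_roots, match_level=masker_match_level)

    if dnh != DNH_NONE:
        return TrialScore(keyword_correct, dnh, masker_overlap=overlap,
                          n_target_content=n_content, n_target_function=n_function)

    alignment = align(target, response, weights)
    content_err, function_err = score_word_errors(alignment)
    morph = score_morpheme_errors(alignment)
    return TrialScore(keyword_correct, dnh,
                      content_errors=content_err, function_errors=function_err,
                      morpheme_errors=morph,
                      alignment=alignment if keep_alignment else None,
                      n_target_content=n_content, n_target_function=n_function)


def score_trials(trials: Sequence[TrialRecord], lexicon: Lexicon,
                 weights: WeightConfig = DEFAULT_WEIGHTS,
                 masker_roots: frozenset[str] | set[str] | None = None,
                 *, masker_match_level: str = "root",
                 keep_alignment: bool = True) -> list[tuple[TrialRecord, "TrialScore"]]:
    """Score every trial; returns (trial, score) pairs in input order."""
    return [(t, score_trial(t, lexicon, weights, masker_roots,
                            masker_match_level=masker_match_level,
                            keep_alignment=keep_alignment))
            for t in trials]
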