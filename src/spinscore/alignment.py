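"""Word-level global alignment of target and response sentences.

A typed response is compared to its target sentence with a Needleman–Wunsch
global alignment over *words* rather than characters.  Because sentences
reuse few words, an exact word match is strong evidence of correct alignment
and is rewarded heavily (+20 by default); near-misses (character edit
distance at most 2 — morphological variants and typos) earn a smaller reward
(+5) so that they still attract the alignment; unrelated word pairs and gaps
are penalized equally (−5).  The result is an ordered sequence of
word-or-gap pairings that downstream error scoring interprets directly:
a response word against a gap is an addition, a target word against a gap is
an omission, and a paired mismatch is a substitution or morpheme change.

The dynamic program maximizes the total score; ties in the traceback are
broken deterministically, preferring a word pairing over a gap in the
target, and that over a gap in the response, which maximizes the number of
word pairings and keeps error counts stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from .lexicon import Token, levenshtein

__all__ = ["WeightConfig", "AlignedPair", "Alignment", "DEFAULT_WEIGHTS",
           "pair_score", "align", "levenshtein"]


@dataclass(frozen=True)
class WeightConfig:
    """Scoring weights for the word-level aligner."""

    match_reward: int = 20
    partial_reward: int = 5
    mismatch_penalty: int = -5
    gap_penalty: int = -5
    partial_max_dist: int = 2

    def __post_init__(self) -> None:
        if not (self.match_reward > self.partial_reward > self.mismatch_penalty):
            raise ValueError("weights must satisfy match > partial > mismatch")
        if self.gap_penalty > 0:
            raise ValueError("gap penalty must be <= 0")
        if self.partial_max_dist < 0:
            raise ValueError("partial_max_dist must be >= 0")


DEFAULT_WEIGHTS = WeightConfig()

# Pair kinds
MATCH = "match"
PARTIAL = "partial"
MISMATCH = "mismatch"
TARGET_GAP = "target_gap"      # gap on the target side: response word is extra
RESPONSE_GAP = "response_gap"  # gap on the response side: target word is missing


@dataclass(frozen=True)
class AlignedPair:
    """One column of the alignment: a target slot and a response slot.

    Exactly one slot may be None (a gap); ``kind`` records how the pair
    scored (match / partial / mismatch / target_gap / response_gap).
    """

    target: Token | None
    response: Token | None
    kind: str

    def __post_init__(self) -> None:
        if self.target is None and self.response is None:
            raise ValueError("a pair cannot be gap-on-both-sides")


@dataclass(frozen=True)
class Alignment:
    pairs: tuple[AlignedPair, ...]
    score: int

    @property
    def target_tokens(self) -> tuple[Token, ...]:
        return tuple(p.target for p in self.pairs if p.target is not None)

    @property
    def response_tokens(self) -> tuple[Token, ...]:
        return tuple(p.response for p in self.pairs if p.response is not None)


@lru_cache(maxsize=1 << 18)
def _cached_lev(a: str, b: str) -> int:
    return levenshtein(a, b)


def pair_score(t: str, r: str, w: WeightConfig = DEFAULT_WEIGHTS) -> int:
    """Score a target word against a response word (both normalized forms)."""
    if t == r:
        return w.match_reward
    if _cached_lev(t, r) <= w.partial_max_dist:
        return w.partial_reward
    return w.mismatch_penalty


def _pair_kind(t: str, r: str, w: WeightConfig) -> str:
    if t == r:
        return MATCH
    if _cached_lev(t, r) <= w.partial_max_dist:
        return PARTIAL
    return MISMATCH


def align(target: Sequence[Token], response: Sequence[Token],
          w: WeightConfig = DEFAULT_WEIGHTS) -> Alignment:
    """Globally align target and response tokens, maximizing total score.

    Either sequence may be empty; aligning against the empty sequence yields
    all gaps.  Scores are computed on normalized forms.  Traceback ties are
    broken in the fixed order pair > target-gap > response-gap.
    """
    n, m = len(target), len(response)
    tn = [t.norm for t in target]
    rn = [r.norm for r in response]
    gap = w.gap_penalty

    # DP over score matrix; score[i][j] = best score of target[:i] vs response[:j]
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ti = tn[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + pair_score(ti, rn[j - 1], w)
            up = prev[j] + gap       # target word vs gap (omission)
            left = row[j - 1] + gap  # response word vs gap (addition)
            row[j] = diag if diag >= up and diag >= left else (up if up >= left else left)

    # Traceback.  Preference at equal score: diagonal pairing, then consuming
    # a response word against a target gap, then a target word against a
    # response gap.
    pairs: list[AlignedPair] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and \
                score[i][j] == score[i - 1][j - 1] + pair_score(tn[i - 1], rn[j - 1], w):
            kind = _pair_kind(tn[i - 1], rn[j - 1], w)
            pairs.append(AlignedPair(target[i - 1], response[j - 1], kind))
            i, j = i - 1, j - 1
        elif j > 0 and score[i][j] == score[i][j - 1] + gap:
            pairs.append(AlignedPair(None, response[j - 1], TARGET_GAP))
            j -= 1
        else:
            pairs.append(AlignedPair(target[i - 1], None, RESPONSE_GAP))
            i -= 1
    pairs.reverse()
    return Alignment(tuple(pairs), score[n][m])
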