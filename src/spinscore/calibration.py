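"""Closed-loop recovery of simulator error rates from pipeline output.

Each simulated error process has a direct readout in the scored trials, so
its generating rate can be re-estimated from pipeline output alone and
compared against the configured value — the package's main self-check that
scoring is calibrated.  Two processes need an inversion step because of the
DNH exclusion rule: a trial whose content words were *all* substituted
surfaces as DNH-Incorrect (the substitutions themselves are never counted),
and one whose content words were all omitted surfaces as DNH-Nothing.  The
estimators below credit those trials with one substitution (resp. omission)
per target content word, which makes the per-word counts exactly binomial
under the generator's independence assumption.
"""

from __future__ import annotations

import math
from typing import Sequence

from .scoring import DNH_INCORRECT, DNH_NONE, DNH_NOTHING, TrialScore

__all__ = ["RECOVERABLE_PROCESSES", "estimate_process_rate", "sampling_band"]

RECOVERABLE_PROCESSES = (
    "dnh_nothing", "dnh_incorrect",
    "content_substitution", "content_addition", "content_omission",
    "function_substitution", "function_addition", "function_omission",
    "morpheme", "keyword_miss", "masker_intrusion",
)


def estimate_process_rate(scores: Sequence[TrialScore], process: str) -> tuple[float, int]:
    """Return (rate estimate, effective trial/word count) for one error process.

    The estimate is the fraction of opportunities on which the process fired,
    assuming it acted alone: per trial for the DNH processes, per target
    content word for content-word and morpheme processes, per target function
    word for function-word processes, per keyword for keyword misses, and per
    DNH-Incorrect response content word for masker intrusion.
    """
    if process not in RECOVERABLE_PROCESSES:
        raise ValueError(f"unknown process {process!r}")
    if not scores:
        raise ValueError("no scored trials given")

    non_dnh = [s for s in scores if s.dnh_status == DNH_NONE]
    nothing = [s for s in scores if s.dnh_status == DNH_NOTHING]
    incorrect = [s for s in scores if s.dnh_status == DNH_INCORRECT]

    if process == "dnh_nothing":
        return len(nothing) / len(scores), len(scores)
    if process == "dnh_incorrect":
        return len(incorrect) / len(scores), len(scores)
    if process == "keyword_miss":
        flags = [b for s in scores for b in s.keyword_correct]
        return 1.0 - sum(flags) / len(flags), len(flags)
    if process == "masker_intrusion":
        matched = sum(s.masker_overlap[0] for s in incorrect if s.masker_overlap)
        total = sum(s.masker_overlap[1] for s in incorrect if s.masker_overlap)
        return (matched / total if total else math.nan), total

    if process.startswith("content_") or process == "morpheme":
        num = 0
        den = sum(s.n_target_content for s in non_dnh)
        if process == "content_substitution":
            num = sum(s.content_errors.substitution for s in non_dnh)
            num += sum(s.n_target_content for s in incorrect)
            den += sum(s.n_target_content for s in incorrect)
        elif process == "content_omission":
            num = sum(s.content_errors.omission for s in non_dnh)
            num += sum(s.n_target_content for s in nothing)
            den += sum(s.n_target_content for s in nothing)
        elif process == "content_addition":
            num = sum(s.content_errors.addition for s in non_dnh)
        else:  # morpheme
            num = sum(s.morpheme_errors for s in non_dnh)
        return (num / den if den else math.nan), den

    # function-word processes (invisible on DNH trials)
    den = sum(s.n_target_function for s in non_dnh)
    kind = process.removeprefix("function_")
    num = sum(getattr(s.function_errors, kind) for s in non_dnh)
    return (num / den if den else math.nan), den


def sampling_band(rate: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation sampling band for a binomial proportion at rate *rate*."""
    half = z * math.sqrt(rate * (1.0 - rate) / n)
    return max(0.0, rate - half), min(1.0, rate + half)
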