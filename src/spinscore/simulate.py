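"""Synthetic listening-session generator.

The package's analyses are exercised end to end on simulated data emulating
a speech-in-noise study: each subject hears three 16-sentence lists of
BKB-style target sentences (3–4 uppercase keywords per sentence, 50 keywords
per list) under three masker conditions — an intelligible single competing
talker (1T), the same talker time-reversed (1T_tr), and speech-shaped noise
(SSN), mixed at −5 dB SNR (carried as metadata only; no audio is ever
synthesized).  The competing talker has a 30-sentence inventory whose
content vocabulary is disjoint from the target vocabulary by construction,
so masker intrusions are identifiable from content-word overlap.

Simulated listeners make errors through independent per-word processes whose
rates are set per group and condition: whole-sentence omissions (typing
nothing, or typing only off-target content drawn from the masker or a decoy
vocabulary), keyword misses, word substitutions / additions / omissions
(content and function words separately), morpheme flips (swapping a content
word for another surface form of the same root, e.g. plural or past tense),
and one-character typos on content words (which the scoring pipeline's spell
corrector is expected to undo).  All randomness flows from an explicit seed
through per-subject substreams.

Default rates reproduce the group-by-condition structure of a depression
(MDD) vs control cohort: a selective excess of masker-confusion errors
(DNH-Incorrect) for the MDD group under the intelligible talker, roughly
70% of off-target content drawn from the masker, and matching keyword
accuracies; see docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, default_lexicon, tokenize
from .scoring import CONDITIONS, GROUPS, TrialRecord

__all__ = ["SessionDesign", "SimulationParams", "Materials",
           "DEFAULT_DESIGN", "default_params", "null_params",
           "generate_materials", "simulate_response", "simulate_cohort",
           "cohort_frame"]


@dataclass(frozen=True)
class SessionDesign:
    """Study-design constants for one session."""

    conditions: tuple[str, ...] = CONDITIONS
    sentences_per_list: int = 16
    keywords_per_list: int = 50
    snr_db: float = -5.0  # metadata only
    masker_sentences_per_talker: int = 30

    @property
    def n_stimuli(self) -> int:
        return self.sentences_per_list * len(self.conditions)


DEFAULT_DESIGN = SessionDesign()


@dataclass(frozen=True)
class SimulationParams:
    """Error-process rates for one group in one condition.

    All rates are probabilities.  ``keyword_hit_rate`` is the probability a
    keyword is transcribed at all (misses surface as content-word
    omissions); the substitution/addition/omission rates apply per word of
    the relevant class; ``morpheme_rate`` flips a content word to a sibling
    form of the same root; ``typo_rate`` applies a one-character typo to a
    content word.  ``masker_intrusion_prob`` is the probability that each
    content word of a DNH-Incorrect response is drawn from the masker
    inventory rather than the decoy vocabulary (intelligible talker only).
    """

    keyword_hit_rate: float = 1.0
    dnh_nothing_rate: float = 0.0
    dnh_incorrect_rate: float = 0.0
    masker_intrusion_prob: float = 0.0
    content_sub_rate: float = 0.0
    content_add_rate: float = 0.0
    content_om_rate: float = 0.0
    function_sub_rate: float = 0.0
    function_add_rate: float = 0.0
    function_om_rate: float = 0.0
    morpheme_rate: float = 0.0
    typo_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        if self.dnh_nothing_rate + self.dnh_incorrect_rate > 1.0:
            raise ValueError("dnh_nothing_rate + dnh_incorrect_rate must be <= 1")


def default_params() -> dict[tuple[str, str], SimulationParams]:
    """Study-condition defaults per (group, condition).

    DNH rates, masker-intrusion probabilities, and keyword hit rates mirror
    the reported group-by-condition means of the emulated study; hit rates
    are solved from accuracy = (1 - p_DNHN - p_DNHI) * hit * (1 - sub) *
    (1 - morph), since DNH trials contribute essentially no correct keywords
    and a substituted or morpheme-flipped keyword is also scored wrong
    (typos are undone by the spell corrector).  Word-level rates are fixed
    plausible values reproducing the reported ordering across conditions.
    """
    dnh_nothing = {("MDD", "1T"): .010, ("MDD", "1T_tr"): .054, ("MDD", "SSN"): .051,
                   ("control", "1T"): .011, ("control", "1T_tr"): .021,
                   ("control", "SSN"): .043}
    dnh_incorrect = {("MDD", "1T"): .265, ("MDD", "1T_tr"): .044, ("MDD", "SSN"): .052,
                     ("control", "1T"): .163, ("control", "1T_tr"): .038,
                     ("control", "SSN"): .034}
    accuracy = {("MDD", "1T"): .652, ("MDD", "1T_tr"): .815, ("MDD", "SSN"): .738,
                ("control", "1T"): .750, ("control", "1T_tr"): .863,
                ("control", "SSN"): .772}
    intrusion = {"MDD": .710, "control": .723}
    morpheme = {"1T": .03, "1T_tr": .02, "SSN": .08}
    sub = .03
    out = {}
    for g in GROUPS:
        for c in CONDITIONS:
            survive = ((1 - dnh_nothing[(g, c)] - dnh_incorrect[(g, c)])
                       * (1 - sub) * (1 - morpheme[c]))
            out[(g, c)] = SimulationParams(
                keyword_hit_rate=round(accuracy[(g, c)] / survive, 4),
                dnh_nothing_rate=dnh_nothing[(g, c)],
                dnh_incorrect_rate=dnh_incorrect[(g, c)],
                masker_intrusion_prob=intrusion[g] if c == "1T" else 0.0,
                content_sub_rate=sub, content_add_rate=.01, content_om_rate=0.0,
                function_sub_rate=.02, function_add_rate=.02, function_om_rate=.05,
                morpheme_rate=morpheme[c], typo_rate=.02)
    return out


def null_params() -> dict[tuple[str, str], SimulationParams]:
    """Both groups behave like the control group (no group effect anywhere)."""
    base = default_params()
    return {(g, c): base[("control", c)] for g in GROUPS for c in CONDITIONS}


# ---------------------------------------------------------------------------
# Materials

# Target content vocabulary used by the sentence templates (base forms; the
# lexicon supplies the sibling forms used for morpheme flips).
TARGET_NOUNS = ("bucket", "table", "daughter", "school", "garden", "kitten",
                "farmer", "ticket", "carpet", "candle", "pencil", "sister")
TARGET_VERBS = ("held", "carried", "cleaned", "painted", "found", "washed",
                "opened", "closed", "filled", "moved")
TARGET_ADJS = ("old", "young", "green", "sweet", "warm", "cold")

MASKER_NOUNS = ("window", "mountain", "river", "doctor", "letter", "summer",
                "market", "dinner", "jacket", "puppy")
MASKER_VERBS = ("watched", "visited", "borrowed", "followed", "answered",
                "listened")

DECOY_WORDS = ("unicorn", "wizard", "planet", "robot", "dragon", "pirate",
               "castle", "rocket", "jump", "whistle", "gallop", "vanish",
               "sparkle", "wander")

FUNCTION_FILLERS = ("the", "a", "his", "her", "to", "on", "in", "with")


@dataclass(frozen=True)
class Materials:
    """Generated stimulus materials: one target list per condition and the
    competing talker's sentence inventory."""

    lists: dict[str, tuple[str, ...]]       # condition -> target sentences
    masker_sentences: tuple[str, ...]       # the 1T talker's inventory
    design: SessionDesign = DEFAULT_DESIGN

    def masker_inventory(self, lexicon: Lexicon, *, level: str = "root") -> frozenset[str]:
        """Content-word inventory of the masker sentences (roots or surfaces)."""
        words: set[str] = set()
        for sent in self.masker_sentences:
            for w in tokenize(sent):
                entry = lexicon.lookup(w)
                if entry is not None and entry[0] == "content":
                    words.add(entry[1] if level == "root" else w)
        return frozenset(words)


def _keyword_counts(design: SessionDesign, rng: np.random.Generator) -> list[int]:
    """3 or 4 keywords per sentence, summing to keywords_per_list."""
    n, total = design.sentences_per_list, design.keywords_per_list
    n_four = total - 3 * n
    if not 0 <= n_four <= n:
        raise ValueError("design not satisfiable with 3-4 keywords per sentence")
    counts = [4] * n_four + [3] * (n - n_four)
    rng.shuffle(counts)
    return counts


def _target_sentence(n_keywords: int, rng: np.random.Generator) -> str:
    """One template sentence with content words uppercased as keywords."""
    n1, n2 = rng.choice(len(TARGET_NOUNS), size=2, replace=False)
    verb = TARGET_VERBS[rng.integers(len(TARGET_VERBS))]
    words = ["the", TARGET_NOUNS[n1].upper(), verb.upper(),
             "the", TARGET_NOUNS[n2].upper()]
    if n_keywords == 4:
        adj = TARGET_ADJS[rng.integers(len(TARGET_ADJS))]
        words.insert(1, adj.upper())
    return " ".join(words)


def generate_materials(design: SessionDesign = DEFAULT_DESIGN,
                       seed: int | np.random.SeedSequence = 0) -> Materials:
    """Generate target lists and the masker inventory, reproducibly from *seed*."""
    rng = np.random.default_rng(seed)
    lists = {}
    for cond in design.conditions:
        sentences = [_target_sentence(k, rng) for k in _keyword_counts(design, rng)]
        lists[cond] = tuple(sentences)
    maskers = []
    for _ in range(design.masker_sentences_per_talker):
        m1, m2 = rng.choice(len(MASKER_NOUNS), size=2, replace=False)
        verb = MASKER_VERBS[rng.integers(len(MASKER_VERBS))]
        maskers.append(f"the {MASKER_NOUNS[m1]} {verb} the {MASKER_NOUNS[m2]}")
    return Materials(lists=lists, masker_sentences=tuple(maskers), design=design)


# ---------------------------------------------------------------------------
# Listener simulation

_TYPO_LETTERS = "qxz"  # rare letters keep typos out-of-vocabulary


def _typo(word: str, lexicon: Lexicon, rng: np.random.Generator) -> str:
    """One-character insertion producing an out-of-vocabulary string."""
    for _ in range(5):
        pos = int(rng.integers(len(word) + 1))
        letter = _TYPO_LETTERS[rng.integers(len(_TYPO_LETTERS))]
        cand = word[:pos] + letter + word[pos:]
        if cand not in lexicon:
            return cand
    return word


_masker_words_cache: dict[int, tuple[str, ...]] = {}


def _masker_content_words(materials: Materials, lexicon: Lexicon) -> tuple[str, ...]:
    cached = _masker_words_cache.get(id(materials))
    if cached is not None:
        return cached
    words = set()
    for sent in materials.masker_sentences:
        for w in tokenize(sent):
            entry = lexicon.lookup(w)
            if entry is not None and entry[0] == "content":
                words.add(w)
    result = tuple(sorted(words))
    _masker_words_cache.clear()  # keep at most one cohort's materials alive
    _masker_words_cache[id(materials)] = result
    return result


def simulate_response(target: str, condition: str, params: SimulationParams,
                      materials: Materials, lexicon: Lexicon,
                      rng: np.random.Generator) -> str:
    """Simulate one typed response to *target* (uppercase keywords)."""
    u = rng.random()
    if u < params.dnh_nothing_rate:
        return ""
    if u < params.dnh_nothing_rate + params.dnh_incorrect_rate:
        masker_words = _masker_content_words(materials, lexicon)
        k = int(rng.integers(2, 5))
        words = []
        for _ in range(k):
            if condition == "1T" and rng.random() < params.masker_intrusion_prob:
                words.append(masker_words[rng.integers(len(masker_words))])
            else:
                words.append(DECOY_WORDS[rng.integers(len(DECOY_WORDS))])
        return " ".join(words)

    out: list[str] = []
    for surface in target.split():
        is_keyword = surface.isupper()
        word = surface.lower()
        entry = lexicon.lookup(word)
        is_content = entry is not None and entry[0] == "content"

        if is_content:
            p_drop = params.content_om_rate
            if is_keyword:
                p_drop = 1.0 - (1.0 - p_drop) * params.keyword_hit_rate
            if rng.random() < p_drop:
                continue
            if rng.random() < params.content_sub_rate:
                word = DECOY_WORDS[rng.integers(len(DECOY_WORDS))]
            elif rng.random() < params.morpheme_rate:
                siblings = [w for w in lexicon.words_with_root(entry[1]) if w != word]
                if siblings:
                    word = siblings[int(rng.integers(len(siblings)))]
            if rng.random() < params.typo_rate:
                word = _typo(word, lexicon, rng)
            out.append(word)
            if rng.random() < params.content_add_rate:
                out.append(DECOY_WORDS[rng.integers(len(DECOY_WORDS))])
        else:
            if rng.random() < params.function_om_rate:
                continue
            if rng.random() < params.function_sub_rate:
                others = [w for w in FUNCTION_FILLERS if w != word]
                word = others[int(rng.integers(len(others)))]
            out.append(word)
            if rng.random() < params.function_add_rate:
                out.append(FUNCTION_FILLERS[int(rng.integers(len(FUNCTION_FILLERS)))])
    return " ".join(out)


def simulate_cohort(params: Mapping[tuple[str, str], SimulationParams] | None = None,
                    n_per_group: int = 40,
                    design: SessionDesign = DEFAULT_DESIGN,
                    seed: int = 0,
                    lexicon: Lexicon | None = None,
                    conditions_subset: Sequence[str] | None = None,
                    ) -> tuple[list[TrialRecord], Materials]:
    """Simulate a full cohort: every subject x condition x sentence.

    Materials are generated once from a sub-seed of *seed*; each subject
    draws from an independent RNG substream, so the output is reproducible
    and insensitive to subject ordering.
    """
    if params is None:
        params = default_params()
    if lexicon is None:
        lexicon = default_lexicon()
    conditions = tuple(conditions_subset or design.conditions)
    root = np.random.SeedSequence(seed)
    mat_seed, subj_seed = root.spawn(2)
    materials = generate_materials(design, mat_seed)
    streams = subj_seed.spawn(2 * n_per_group)

    trials: list[TrialRecord] = []
    k = 0
    for group in GROUPS:
        for i in range(n_per_group):
            subject = f"{group}{i + 1:03d}"
            rng = np.random.default_rng(streams[k]); k += 1
            for cond in conditions:
                p = params[(group, cond)]
                for sent in materials.lists[cond]:
                    resp = simulate_response(sent, cond, p, materials, lexicon, rng)
                    trials.append(TrialRecord(
                        subject_id=subject, group=group, condition=cond,
                        target=sent, response=resp,
                        masker_id="talkerA" if cond == "1T" else None))
    return trials, materials


def cohort_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial table as a DataFrame in the on-disk TSV column order."""
    return pd.DataFrame([{
        "subject_id": t.subject_id, "group": t.group, "condition": t.condition,
        "target": t.target, "response": t.response,
        "masker_id": t.masker_id or ""} for t in trials])
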