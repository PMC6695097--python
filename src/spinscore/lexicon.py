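"""Tokenization, word-class tagging, and typo correction for typed transcripts.

Typed listener responses are scored against target sentences word by word, so
every sentence is first reduced to a sequence of :class:`Token` objects
carrying a normalized form (case-folded, edge punctuation stripped), a word
class, and a root (lemma).  Word classes follow the standard psycholinguistic
split: *content* words (nouns, verbs, adjectives, adverbs), *function* words
(closed-class), and forms of the verb "to be", which are kept apart because
they are excluded from content-word matching when classifying whole-sentence
omissions.

Tagging is a lookup into a pluggable TSV lexicon rather than a statistical
POS tagger: the test materials use a small, closed vocabulary, and a lexicon
makes the root (lemma) relation explicit and auditable.  Words missing from
the lexicon default to content class with root equal to their normalized
form — unknown words in typed responses are most often misspelled content
words, and the spell corrector runs before any error is attributed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import edlib

__all__ = [
    "Token",
    "Lexicon",
    "BE_FORMS",
    "EDGE_PUNCT",
    "load_lexicon",
    "default_lexicon",
    "tokenize",
    "tag_tokens",
    "correct_spelling",
    "levenshtein",
]

#: Closed list of forms of "to be".  These are never counted as content words
#: when deciding whether a response reproduced any target content, and they
#: are scored with function words in word-level error counts.
BE_FORMS = frozenset({"be", "am", "is", "are", "was", "were", "been", "being",
                      "'s", "'m", "'re"})

#: Punctuation stripped from token edges (typed responses carry stray
#: periods, commas and quotes; apostrophes survive only inside clitics).
EDGE_PUNCT = ".,!?;:\"'()[]"

WORD_CLASSES = ("content", "function", "be_form")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost character edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


@dataclass(frozen=True)
class Token:
    """One word of a target, response, or masker sentence."""

    surface: str
    norm: str
    cls: str  # "content" | "function" | "be_form"
    root: str
    is_keyword: bool = False

    def __post_init__(self) -> None:
        if not self.norm or any(c.isspace() for c in self.norm):
            raise ValueError(f"norm must be non-empty and whitespace-free: {self.norm!r}")
        if self.cls not in WORD_CLASSES:
            raise ValueError(f"unknown word class {self.cls!r}")


class Lexicon:
    """Mapping from normalized word to (word class, root).

    Roots are fixed points: every root stored for an entry is itself a
    resolvable word whose root is itself.  Entries may optionally carry a
    corpus frequency used to rank spell-correction candidates.
    """

    def __init__(self, entries: dict[str, tuple[str, str]],
                 frequencies: dict[str, float] | None = None):
        self._entries = dict(entries)
        self._freq = dict(frequencies or {})
        for word, (cls, root) in self._entries.items():
            if cls not in WORD_CLASSES:
                raise ValueError(f"unknown class {cls!r} for {word!r}")
            root_entry = self._entries.get(root)
            if root_entry is None or root_entry[1] != root:
                raise ValueError(
                    f"root {root!r} of {word!r} is not a fixed point of the lexicon")

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._entries)

    def __contains__(self, word: str) -> bool:
        return word in self._entries or word in BE_FORMS

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, word: str) -> tuple[str, str] | None:
        """Return (cls, root) for *word*, or None if absent."""
        return self._entries.get(word)

    def root(self, word: str) -> str:
        entry = self._entries.get(word)
        return entry[1] if entry is not None else word

    def frequency(self, word: str) -> float:
        return self._freq.get(word, 0.0)

    def words_with_root(self, root: str) -> list[str]:
        """All entry words sharing *root*, in lexicographic order."""
        return sorted(w for w, (_, r) in self._entries.items() if r == root)

    def words_of_class(self, cls: str) -> list[str]:
        return sorted(w for w, (c, _) in self._entries.items() if c == cls)


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon TSV: ``word<TAB>class<TAB>root[<TAB>frequency]``.

    Raises FileNotFoundError for a missing file and ValueError for a
    malformed row, an unknown class label, or a duplicate word.
    """
    path = Path(path)
    entries: dict[str, tuple[str, str]] = {}
    freqs: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 tab-separated fields, "
                    f"got {len(fields)}")
            word, cls, root = fields[0], fields[1], fields[2]
            if cls not in WORD_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown word class {cls!r}")
            if word in entries:
                raise ValueError(f"{path}:{lineno}: duplicate word {word!r}")
            entries[word] = (cls, root)
            if len(fields) == 4:
                freqs[word] = float(fields[3])
    return Lexicon(entries, freqs)


def default_lexicon() -> Lexicon:
    """The lexicon shipped with the package (test sentences + simulator vocabulary)."""
    resource = importlib.resources.files("spinscore.data").joinpath("lexicon.tsv")
    with importlib.resources.as_file(resource) as path:
        return load_lexicon(path)


def _normalize(piece: str) -> str:
    piece = piece.casefold()
    if piece in BE_FORMS:  # clitics like 's keep their apostrophe
        return piece
    return piece.strip(EDGE_PUNCT)


def tokenize(text: str) -> list[str]:
    """Split a sentence into normalized word strings.

    Whitespace split; edge punctuation stripped; case-folded; empty pieces
    dropped; order preserved.  The empty string yields an empty list.
    """
    out = []
    for piece in text.split():
        norm = _normalize(piece)
        if norm:
            out.append(norm)
    return out


def _surface_tokens(text: str) -> list[tuple[str, str]]:
    """(surface, norm) pairs, dropping pieces that normalize to nothing."""
    out = []
    for piece in text.split():
        norm = _normalize(piece)
        if norm:
            out.append((piece, norm))
    return out


def _tag_one(surface: str, norm: str, lexicon: Lexicon, is_keyword: bool) -> Token:
    if norm in BE_FORMS:
        return Token(surface, norm, "be_form", norm, is_keyword)
    entry = lexicon.lookup(norm)
    if entry is None:
        return Token(surface, norm, "content", norm, is_keyword)
    cls, root = entry
    return Token(surface, norm, cls, root, is_keyword)


def tag_tokens(words: Sequence[str], lexicon: Lexicon) -> list[Token]:
    """Resolve word class and root for each word via the lexicon.

    Be-forms always receive ``cls="be_form"``; words absent from the lexicon
    fall back to ``cls="content"`` with root equal to the word itself.
    """
    return [_tag_one(w, _normalize(w) or w, lexicon, False) for w in words]


def tag_sentence(text: str, lexicon: Lexicon,
                 keyword_norms: Iterable[str] | None = None) -> list[Token]:
    """Tokenize and tag a sentence, marking keywords.

    By convention keywords are written in UPPERCASE in the target text
    (``The BUCKETS HOLD WATER``); alternatively an explicit set of keyword
    norms may be supplied and overrides the case convention.
    """
    explicit = set(keyword_norms) if keyword_norms is not None else None
    tokens = []
    for surface, norm in _surface_tokens(text):
        if explicit is not None:
            is_kw = norm in explicit
        else:
            stripped = surface.strip(EDGE_PUNCT)
            is_kw = stripped.isupper() and any(c.isalpha() for c in stripped)
        tokens.append(_tag_one(surface, norm, lexicon, is_kw))
    return tokens


def _spell_candidates(word: str, lexicon: Lexicon, max_dist: int = 2) -> list[str]:
    """Lexicon words within edit distance *max_dist*, ranked deterministically.

    Tiers by ascending edit distance; within a tier, descending corpus
    frequency then lexicographic order — a fixed stand-in for a spell
    checker's "first suggestion" ranking.
    """
    tiers: dict[int, list[str]] = {d: [] for d in range(1, max_dist + 1)}
    for cand in lexicon.vocabulary:
        d = levenshtein(word, cand)
        if 1 <= d <= max_dist:
            tiers[d].append(cand)
    ranked = []
    for d in range(1, max_dist + 1):
        ranked.extend(sorted(tiers[d], key=lambda w: (-lexicon.frequency(w), w)))
    return ranked


def correct_spelling(response: Sequence[Token], target: Sequence[Token],
                     lexicon: Lexicon) -> list[Token]:
    """Replace out-of-vocabulary response words that misspell a target content word.

    For each response token whose norm is not in the lexicon, candidate
    corrections are generated at edit distance 1 then 2; the token is
    replaced by the first candidate equal to the norm of some content-class
    target token, and left unchanged otherwise.  In-vocabulary tokens are
    never touched, so correctly spelled confusions (homophones) are never
    "fixed" into matches.
    """
    target_content = {t.norm for t in target if t.cls == "content"}
    out: list[Token] = []
    for tok in response:
        if tok.norm in lexicon:
            out.append(tok)
            continue
        replacement = None
        for cand in _spell_candidates(tok.norm, lexicon):
            if cand in target_content:
                replacement = cand
                break
        if replacement is None:
            out.append(tok)
        else:
            out.append(_tag_one(tok.surface, replacement, lexicon, tok.is_keyword))
    return out
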