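"""Readers, writers, and run configuration.

On-disk formats are deliberately plain text:

* trial tables: TSV with columns ``subject_id  group  condition  target
  response  [masker_id]`` (keywords uppercase in the target, responses may
  be empty); a header row is optional on input and always written on output;
* masker inventories: one sentence per line, one file per condition/talker
  (``maskers_1T.txt``);
* per-trial scores: JSON-lines, one object per trial including the
  alignment as ``[target_word | null, response_word | null, kind]`` triples;
* subject summaries and group tables: TSV; permutation-test results: JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .aggregate import SubjectConditionSummary, summaries_frame
from .alignment import WeightConfig
from .scoring import ErrorCounts, TrialRecord, TrialScore

__all__ = [
    "RunConfig", "read_trials", "write_trials",
    "read_masker_sentences", "write_masker_sentences", "masker_inventory_from_file",
    "score_to_json", "write_scores_jsonl", "read_scores_jsonl",
    "write_summary_tsv", "write_manifest",
]

TRIAL_COLUMNS = ("subject_id", "group", "condition", "target", "response", "masker_id")


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration; the defaults reproduce the reference scheme
    (+20 match / +5 partial / −5 mismatch / −5 gap / partial distance ≤ 2,
    root-level masker matching)."""

    weights: WeightConfig = field(default_factory=WeightConfig)
    lexicon_path: str | None = None          # None -> packaged lexicon
    masker_match_level: str = "root"         # "root" | "surface"
    n_perm: int = 10_000
    seed: int = 0
    focal_condition: str = "1T"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        weights = WeightConfig(**raw.pop("weights", {}))
        return cls(weights=weights, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial TSV (header optional; empty responses preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     header=None, skip_blank_lines=True)
    if df.empty:
        raise ValueError(f"{path}: no trials found")
    if df.iloc[0, 0] == "subject_id":
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"{path}: no trials found")
    if df.shape[1] == 5:
        df[5] = ""
    if df.shape[1] != 6:
        raise ValueError(f"{path}: expected 5 or 6 tab-separated columns, "
                         f"got {df.shape[1]}")
    df.columns = TRIAL_COLUMNS
    trials = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            trials.append(TrialRecord(
                subject_id=row.subject_id, group=row.group, condition=row.condition,
                target=row.target, response=row.response,
                masker_id=row.masker_id or None))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return trials


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    rows = [{"subject_id": t.subject_id, "group": t.group, "condition": t.condition,
             "target": t.target, "response": t.response,
             "masker_id": t.masker_id or ""} for t in trials]
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_masker_sentences(path: str | Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_masker_sentences(sentences: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(s + "\n" for s in sentences), encoding="utf-8")


def masker_inventory_from_file(path: str | Path, lexicon, *,
                               level: str = "root") -> frozenset[str]:
    """Content-word inventory (roots or surfaces) of a masker sentence file."""
    from .lexicon import tokenize
    words: set[str] = set()
    for sent in read_masker_sentences(path):
        for w in tokenize(sent):
            entry = lexicon.lookup(w)
            if entry is not None and entry[0] == "content":
                words.add(entry[1] if level == "root" else w)
    return frozenset(words)


def score_to_json(trial: TrialRecord, score: TrialScore) -> dict:
    pairs = None
    if score.alignment is not None:
        pairs = [[p.target.norm if p.target else None,
                  p.response.norm if p.response else None,
                  p.kind] for p in score.alignment.pairs]
    return {
        "subject_id": trial.subject_id, "group": trial.group,
        "condition": trial.condition, "target": trial.target,
        "response": trial.response, "masker_id": trial.masker_id,
        "keyword_correct": list(score.keyword_correct),
        "dnh_status": score.dnh_status,
        "masker_overlap": list(score.masker_overlap) if score.masker_overlap else None,
        "content_errors": dataclasses.asdict(score.content_errors)
            if score.content_errors else None,
        "function_errors": dataclasses.asdict(score.function_errors)
            if score.function_errors else None,
        "morpheme_errors": score.morpheme_errors,
        "n_target_content": score.n_target_content,
        "n_target_function": score.n_target_function,
        "alignment": pairs,
        "alignment_score": score.alignment.score if score.alignment else None,
    }


def write_scores_jsonl(records: Iterable[tuple[TrialRecord, TrialScore]],
                       path: str | Path) -> int:
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for trial, score in records:
            fh.write(json.dumps(score_to_json(trial, score)) + "\n")
            n += 1
    return n


def read_scores_jsonl(path: str | Path) -> list[tuple[TrialRecord, TrialScore]]:
    """Round-trip reader for the per-trial JSON-lines (alignment tokens are
    not reconstructed; summaries do not need them)."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            trial = TrialRecord(d["subject_id"], d["group"], d["condition"],
                                d["target"], d["response"], d["masker_id"])
            score = TrialScore(
                keyword_correct=tuple(d["keyword_correct"]),
                dnh_status=d["dnh_status"],
                masker_overlap=tuple(d["masker_overlap"]) if d["masker_overlap"] else None,
                content_errors=ErrorCounts(**d["content_errors"])
                    if d["content_errors"] else None,
                function_errors=ErrorCounts(**d["function_errors"])
                    if d["function_errors"] else None,
                morpheme_errors=d["morpheme_errors"],
                n_target_content=d["n_target_content"],
                n_target_function=d["n_target_function"])
            out.append((trial, score))
    return out


def write_summary_tsv(summaries: Sequence[SubjectConditionSummary] | pd.DataFrame,
                      path: str | Path) -> None:
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_manifest(path: str | Path, *, seed: int, config: RunConfig | None = None,
                   extra: dict | None = None) -> None:
    import spinscore
    manifest = {"package": "spinscore", "version": spinscore.__version__,
                "seed": seed}
    if config is not None:
        manifest["config"] = config.to_dict()
        manifest["config_hash"] = config.content_hash()
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
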