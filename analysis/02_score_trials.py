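#!/usr/bin/env python
"""Score every simulated trial: spell correction, keyword accuracy, DNH
classification, masker overlap, and word-/morpheme-level error counts.

Reads results/cohort/, writes results/scored/trial_scores.jsonl plus the
per-subject summary table.
"""

from collections import Counter
from pathlib import Path

import spinscore as sp

IN = Path("results/cohort")
OUT = Path("results/scored")


def main() -> None:
    lexicon = sp.default_lexicon()
    trials = sp.read_trials(IN / "trials.tsv")
    inventory = sp.masker_inventory_from_file(IN / "maskers_1T.txt", lexicon)
    records = sp.score_trials(trials, lexicon, masker_roots=inventory)

    OUT.mkdir(parents=True, exist_ok=True)
    n = sp.write_scores_jsonl(records, OUT / "trial_scores.jsonl")
    summaries = sp.summarize_records(records)
    sp.write_summary_tsv(summaries, OUT / "subject_summaries.tsv")

    tallies = Counter(s.dnh_status for _, s in records)
    print(f"scored {n} trials; DNH tallies: {dict(sorted(tallies.items()))}")
    kw = [b for _, s in records for b in s.keyword_correct]
    print(f"overall keyword accuracy: {sum(kw) / len(kw):.3f}")
    print(f"wrote {OUT}/trial_scores.jsonl and subject_summaries.tsv")


if __name__ == "__main__":
    main()
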