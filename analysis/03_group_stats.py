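#!/usr/bin/env python
"""Group-level descriptives and permutation interaction tests.

Reads results/scored/trial_scores.jsonl; writes results/stats/: the
group-by-condition mean +/- SD table and the permutation test of the
group-by-condition interaction (single-talker condition vs the rest) for
each of the six analysis metrics.
"""

import json
from pathlib import Path

import spinscore as sp

IN = Path("results/scored")
OUT = Path("results/stats")
SEED = 1
N_PERM = 10_000


def main() -> None:
    records = sp.read_scores_jsonl(IN / "trial_scores.jsonl")
    summaries = sp.summarize_records(records)
    df = sp.summaries_frame(summaries)

    OUT.mkdir(parents=True, exist_ok=True)
    table = sp.group_table(df, metrics=sp.METRICS + ("masker_overlap",))
    sp.write_summary_tsv(table, OUT / "group_table.tsv")

    show = table.set_index(["group", "condition"])
    for metric in ("keyword_accuracy", "p_dnh_incorrect", "masker_overlap"):
        print(f"\n{metric} (mean +/- SD):")
        for (g, c), row in show.iterrows():
            m, s = row[f"{metric}_mean"], row[f"{metric}_std"]
            print(f"  {g:8s} {c:6s} {m:6.3f} +/- {s:.3f}"
                  if m == m else f"  {g:8s} {c:6s}    --")

    results = sp.run_interaction_tests(df, sp.METRICS, n_perm=N_PERM, seed=SEED)
    (OUT / "interaction_tests.json").write_text(
        json.dumps(results, indent=2) + "\n", encoding="utf-8")
    print("\npermutation interaction tests (1T vs mean of 1T_tr, SSN):")
    for r in results:
        flag = " *" if r["p"] < 0.05 else ""
        print(f"  {r['metric']:22s} stat={r['statistic']:+.4f}  p={r['p']:.4g}{flag}")
    print(f"\nwrote {OUT}/group_table.tsv and interaction_tests.json")


if __name__ == "__main__":
    main()
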