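#!/usr/bin/env python
"""Simulate the study cohort: 40 subjects per group (MDD, control), each
hearing three 16-sentence lists under the 1T, 1T_tr, and SSN maskers, with
the default group-by-condition error rates.

Writes results/cohort/: trials.tsv, targets_<condition>.txt, maskers_1T.txt,
and a manifest recording the seed.
"""

import sys
from pathlib import Path

import spinscore as sp

SEED = 1
N_PER_GROUP = 40
OUT = Path("results/cohort")


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    OUT.mkdir(parents=True, exist_ok=True)
    trials, materials = sp.simulate_cohort(n_per_group=N_PER_GROUP, seed=seed)
    sp.write_trials(trials, OUT / "trials.tsv")
    sp.write_masker_sentences(materials.masker_sentences, OUT / "maskers_1T.txt")
    for cond, sentences in materials.lists.items():
        (OUT / f"targets_{cond}.txt").write_text(
            "".join(s + "\n" for s in sentences), encoding="utf-8")
    sp.write_manifest(OUT / "manifest.json", seed=seed,
                      extra={"n_per_group": N_PER_GROUP, "n_trials": len(trials)})
    print(f"simulated {len(trials)} trials "
          f"({N_PER_GROUP}/group x 3 conditions x 16 sentences, seed {seed})")
    print(f"wrote {OUT}/trials.tsv and stimulus materials")


if __name__ == "__main__":
    main()
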