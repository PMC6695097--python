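# Methods

## Problem setting

In speech-perception-in-noise (SPIN) experiments, listeners hear short
target sentences mixed with an interfering masker and type what they heard.
Beyond the standard keyword-accuracy score, the *pattern* of transcription
errors is informative: a listener defeated by energetic masking tends to
omit or garble words, whereas a listener captured by an intelligible
competing talker reports words from the *masker* instead of the target.
`spinscore` implements a complete error-analysis pipeline for such typed
transcripts, plus a synthetic listener simulator so the pipeline can be
validated end to end without any proprietary recordings or participant
data.

The emulated design has two groups (participants with major depressive
disorder, MDD, and neurotypical controls) and three masker conditions: an
intelligible single competing talker (1T), the same talker time-reversed
(1T_tr, unintelligible but spectro-temporally matched), and speech-shaped
noise (SSN). Each subject hears three 16-sentence BKB-style lists (3–4
uppercase keywords per sentence, 50 keywords per list; 48 stimuli total) at
−5 dB SNR. The SNR and audio chain are metadata only — no signal processing
is performed here.

## Scoring pipeline

Each trial is processed as follows.

**Tokenization and tagging.** Sentences are whitespace-split; edge
punctuation (`.,!?;:"'()[]`) is stripped, case is folded, and empty pieces
are dropped (apostrophes survive inside clitics such as `'s`). Words are
tagged by lookup in a TSV lexicon as *content* (nouns, verbs, adjectives,
adverbs), *function* (closed-class), or a form of "to be" (`be am is are
was were been being 's 'm 're`, a fixed list). Be-forms are excluded from
content-word matching and scored with function words. Words missing from
the lexicon default to content class with root equal to the word itself:
unknown strings in typed responses are most often misspelled content words,
and the spell corrector runs before any error is attributed. The lexicon
also carries each word's root (lemma); roots are fixed points of the
lexicon. Hyphenated words are kept whole; numerals are content words.

**Spell correction.** For each response word absent from the lexicon,
candidate corrections are all lexicon words at character edit distance 1,
then 2, each tier ordered by descending corpus frequency (when the lexicon
provides one) then lexicographically — a deterministic stand-in for a spell
checker's "first suggestion". The word is replaced by the first candidate
equal to a content word of the target sentence, otherwise left unchanged.
Correctly spelled words are never replaced, so homophone confusions are
never silently repaired into matches.

**Keyword accuracy.** A keyword is correct iff its exact normalized form
appears in the response (position-independent); each response word can
satisfy at most one keyword, and any morphological change makes the keyword
wrong.

**DNH classification.** If no response content word shares a *root* with
any target content word, the trial is a whole-sentence omission ("Did Not
Hear"): *DNH-Nothing* when the response contains no content words at all,
*DNH-Incorrect* when it contains content words, none from the target. DNH
trials are excluded from word- and morpheme-level scoring. For
DNH-Incorrect trials in the 1T condition (the only condition with an
intelligible masker), the response's content words are compared against the
content-word root inventory of the full masker sentence set, yielding a
(matched, total) masker-overlap count. Root-level matching is the default
for both decisions; surface-level masker matching is available via
configuration.

**Alignment.** Target and response are aligned with a Needleman–Wunsch
global alignment over *words*. An exact word match scores +20 (sentences
reuse few words, so an exact match is strong evidence of correct
alignment); a near-miss at character edit distance ≤ 2 — morphological
variants and residual typos — scores +5; unrelated pairs and gaps score −5.
Weights and the partial-match threshold are configurable; these defaults
are the package's reference scheme. Scoring is on normalized forms after
spell correction; gap costs are linear (no affine extension). Traceback
ties are broken deterministically — word pairing over response-word-vs-gap
over target-word-vs-gap — which maximizes the number of pairings and keeps
downstream counts stable. Edit distance is computed with `edlib`
(unit-cost, character-level).

**Error counting.** Per aligned pair: a response word against a gap is an
*addition* (attributed to the response word's class); a target word against
a gap is an *omission* (target word's class); two paired function words
that are not identical are a function *substitution*; two paired content
words with different roots are a content *substitution*; two paired content
words with the same root but different forms (pluralization, tense) are a
*morpheme error* — never also a substitution. A cross-class pairing is a
substitution attributed to the target word's class, since errors are
counted against the target sentence.

## Aggregation and inference

Per subject × condition: keyword accuracy; the proportions of sentences
classified DNH-Nothing and DNH-Incorrect (over all sentences presented);
and mean errors per sentence for content words, function words, and
morphemes over the *non-DNH* sentences only, pooling substitution +
addition + omission within each word class. Masker overlap is pooled
(Σmatched / Σtotal) across a subject's DNH-Incorrect 1T trials and is
missing when there are none. Cells with no data stay missing — no
imputation. Group descriptives are means and sample SDs (n−1) of the
per-subject summaries, so each subject weighs equally regardless of trial
counts.

Group inference is a permutation test of the group-by-condition
interaction: the statistic is the difference of group differences between a
focal condition (default 1T) and the mean of the remaining conditions;
the null permutes subject group labels, keeping each subject's condition
profile intact; the two-sided p-value uses the add-one estimator
p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm), which cannot be zero. This
deliberately replaces mixed-effects modeling: those fits are standard
off-the-shelf analyses of the exported per-subject table (which this
package writes as TSV precisely so they can be run elsewhere), whereas the
permutation test keeps the package self-contained, exact under
exchangeability, and assumption-light. A known consequence: it tests the
subject-level summaries, not trial-level variance components.

## The synthetic listener

`simulate_response` draws, per trial: with probability `dnh_nothing_rate`
an empty response; else with probability `dnh_incorrect_rate` a response of
2–4 content words drawn from the masker inventory (each with probability
`masker_intrusion_prob`, 1T only) or from a decoy vocabulary; otherwise a
copy of the target corrupted by independent per-word processes — keyword
misses (probability 1 − `keyword_hit_rate`, realized as omissions),
substitutions (content words → decoys, function words → other function
words), additions (one insertion opportunity after each word of the class),
omissions, morpheme flips (content word → another lexicon form of the same
root; every generator content word has at least one sibling form), and
one-character typos on content words (inserting a rare letter, always
producing an out-of-lexicon string that the spell corrector is expected to
restore). Substitution takes precedence over a morpheme flip on the same
word, so the effective flip rate is (1 − sub) × morph.

Target, masker, and decoy content vocabularies are pairwise disjoint by
construction, which makes every process identifiable: an off-target
response cannot accidentally match the target, and `masker_intrusion_prob`
is estimable from the overlap statistic alone. Sentences are built from
two templates (det + NOUN + VERB + det + NOUN, optionally with an
ADJECTIVE) — 14 three-keyword and 2 four-keyword sentences per list, giving
exactly 50 keywords. Template generation keeps every word taggable by the
packaged ~200-word lexicon. All randomness flows from one seed through
`numpy` `SeedSequence` substreams, one per subject, so cohorts are
reproducible and insensitive to subject order.

What the simulator does *not* emulate: between-subject rate heterogeneity
(all subjects in a cell share one rate vector, so simulated SDs are purely
binomial and smaller than real cohorts'), semantically driven confusions,
word-order errors, response-length coupling, and anything acoustic.
Passing closed-loop tests therefore shows the *scoring* is correct and
calibrated, not that real listeners behave like the generator.

### Default rates

Defaults encode the emulated study's group-by-condition structure: DNH
rates per cell (e.g. DNH-Incorrect 0.265 for MDD vs 0.163 for controls in
1T, and 0.03–0.05 elsewhere — a selective masker-confusion excess),
masker-intrusion probabilities of 0.710 / 0.723, and keyword hit rates
solved per cell from

    accuracy = (1 − p_DNHN − p_DNHI) · hit · (1 − sub) · (1 − morph)

since a DNH trial contributes no correct keywords and a substituted or
morpheme-flipped keyword is also scored wrong (typos are undone by the
corrector). Word-level rates are fixed plausible values (content sub 0.03,
content add 0.01, function sub/add 0.02, function omission 0.05, typo
0.02, morpheme 0.03 / 0.02 / 0.08 for 1T / 1T_tr / SSN) chosen once to
reproduce the reported ordering of error types across conditions — e.g.
morpheme errors peaking under SSN. The "null cohort" configuration gives
both groups the control parameters.

## Calibration checks and problem sizes

`calibration.estimate_process_rate` inverts each process from scored output
alone. Two inversions deserve note: a trial whose content words were *all*
substituted surfaces as DNH-Incorrect (its substitutions are never counted
directly), and one whose content words were all omitted surfaces as
DNH-Nothing; the estimators credit such trials with one substitution
(resp. omission) per target content word, making the per-word counts
exactly binomial under the generator's independence assumptions.

The closed-loop test runs every process alone at rates 0.1 and 0.3 with 20
subjects × 16 trials and checks each estimate against its binomial sampling
band. With 22 probes, bands are applied family-wise at 95% (Bonferroni,
two-sided z ≈ 3.06 per probe): testing 22 unbiased estimators each at a
marginal 95% band would fail most runs by chance alone, while any real
scoring bias at these n (≈ 320–1000 opportunities per probe) produces |z|
well beyond the family-wise band.

Power and size of the permutation interaction test are checked by
replication at the study's scale (40 subjects/group, full 48-trial
sessions): 100 cohorts with the default (group-differentiated) parameters
must reject at α = 0.05 for `p_dnh_incorrect` in ≥ 80% of replicates, and
200 null cohorts must reject in 1–11% (the 99% binomial band around the
nominal level). Replicates use 199 permutations each — enough for an exact
α = 0.05 decision — while the analysis drivers default to 10,000. These
problem sizes keep the full validation suite at a few minutes on one core.

## Numerical and degenerate-input choices

* Integer scores throughout the aligner; no floating point in the DP.
* Aligning any sentence against an empty one yields all gaps (score =
  length × gap penalty); two empty sentences give an empty alignment with
  score 0.
* Sentences with no marked keywords yield an empty keyword vector and a
  missing (not zero) keyword accuracy.
* A subject cell where every trial is DNH has missing error means; a group
  cell with one subject has a missing SD.
* Duplicate keywords consume matching response words one-for-one.
* Spell-correction candidate ties are broken by frequency then
  lexicographic order; tier 1 (distance 1) is exhausted before tier 2.

## Known limitations

* Tagging is lexicon lookup, not statistical POS tagging; coverage of free
  text requires extending the TSV (the packaged lexicon covers the test
  materials and generator vocabulary).
* The aligner is word-level and global; transposed words score as two
  errors, and local rearrangements are not modeled.
* Masker overlap compares against the talker's full sentence inventory,
  not the specific excerpt played on a trial (configurable in principle;
  per-trial excerpts are not modeled by the generator).
* Group inference addresses one planned contrast (focal condition vs rest);
  users needing the full factorial inference should export the summary TSV
  to a mixed-model workflow.
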