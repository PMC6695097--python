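"""Trial scoring: keywords, DNH classification, masker overlap, and
word-/morpheme-level error counts."""

import numpy as np
import pytest

import spinscore as sp
from spinscore.alignment import TARGET_GAP, RESPONSE_GAP, MATCH, PARTIAL, MISMATCH


def tag(sentence, lexicon, keywords=None):
    return sp.tag_sentence(sentence, lexicon, keywords)


class TestScoreKeywords:
    def test_morphological_variant_is_wrong(self, lexicon):
        target = tag("the BUCKETS HOLD WATER", lexicon)
        response = tag("the bucket hold water", lexicon)
        assert sp.score_keywords(target, response) == (False, True, True)

    def test_identity_all_correct(self, lexicon):
        target = tag("the BUCKETS HOLD WATER", lexicon)
        assert sp.score_keywords(target, tag("the buckets hold water", lexicon)) \
            == (True, True, True)

    def test_duplicate_keywords_consume_one_for_one(self, lexicon):
        target = tag("the dog saw the dog", lexicon, keywords={"dog"})
        response = tag("dog", lexicon)
        assert sp.score_keywords(target, response) == (True, False)

    def test_order_and_function_insertions_irrelevant(self, lexicon):
        target = tag("the BUCKETS HOLD WATER", lexicon)
        response = tag("water the with buckets a hold", lexicon)
        assert sp.score_keywords(target, response) == (True, True, True)


class TestClassifyDnh:
    def test_empty_response_is_dnh_nothing(self, lexicon):
        assert sp.classify_dnh(tag("he broke his leg", lexicon), []) == "dnh_nothing"

    def test_off_target_content_is_dnh_incorrect(self, lexicon):
        t = tag("the daughter set the table", lexicon)
        r = tag("can go very fast", lexicon)
        assert sp.classify_dnh(t, r) == "dnh_incorrect"

    def test_root_level_match_avoids_dnh(self, lexicon):
        t = tag("the daughter set the table", lexicon)
        r = tag("the daughters sat", lexicon)
        assert sp.classify_dnh(t, r) == "none"

    def test_be_forms_never_count_as_content(self, lexicon):
        t = tag("a man is turning the faucet", lexicon)
        r = tag("is was be", lexicon)  # only be-forms: no content transcribed
        assert sp.classify_dnh(t, r) == "dnh_nothing"

    def test_function_words_only_is_dnh_nothing(self, lexicon):
        t = tag("he broke his leg", lexicon)
        assert sp.classify_dnh(t, tag("the the a", lexicon)) == "dnh_nothing"


class TestMaskerOverlap:
    def test_full_containment(self, lexicon):
        r = tag("go fast", lexicon)
        assert sp.masker_overlap(r, {"go", "fast", "pie"}) == (2, 2)

    def test_disjoint(self, lexicon):
        r = tag("unicorn", lexicon)
        assert sp.masker_overlap(r, {"pie"}) == (0, 1)

    def test_partial_intersection(self, lexicon):
        r = tag("go unicorn", lexicon)
        assert sp.masker_overlap(r, {"go"}) == (1, 2)

    def test_root_vs_surface_level(self, lexicon):
        r = tag("went", lexicon)  # root "go"
        assert sp.masker_overlap(r, {"go"}, match_level="root") == (1, 1)
        assert sp.masker_overlap(r, {"go"}, match_level="surface") == (0, 1)


class TestWordAndMorphemeErrors:
    def test_cross_class_pair_attributed_to_target_class(self, lexicon):
        # content target word paired with a function response word
        t = tag("the daughter held the table", lexicon)
        r = tag("the with held the table", lexicon)
        a = sp.align(t, r)
        content, function = sp.score_word_errors(a)
        assert (content.substitution, function.substitution) == (1, 0)

    def test_morpheme_error_not_double_counted_as_substitution(self, lexicon):
        t = tag("the daughter set the table", lexicon)
        r = tag("the daughters set the table", lexicon)
        a = sp.align(t, r)
        content, function = sp.score_word_errors(a)
        assert content.substitution == 0
        assert sp.score_morpheme_errors(a) == 1

    def test_distant_same_root_pair_is_still_morpheme_error(self, lexicon):
        # "carried" vs "carry" is 3 edits apart but shares a root
        t = tag("the sister carried the candle", lexicon)
        r = tag("the sister carry the candle", lexicon)
        a = sp.align(t, r)
        assert sp.score_morpheme_errors(a) == 1
        content, _ = sp.score_word_errors(a)
        assert content.substitution == 0

    def test_conservation_of_tokens(self, lexicon):
        rng = np.random.default_rng(3)
        vocab = ["the", "daughter", "daughters", "held", "table", "a", "unicorn"]
        for _ in range(100):
            t = [vocab[i] for i in rng.integers(0, len(vocab), rng.integers(1, 7))]
            r = [vocab[i] for i in rng.integers(0, len(vocab), rng.integers(0, 7))]
            tt, rt = sp.tag_tokens(t, lexicon), sp.tag_tokens(r, lexicon)
            a = sp.align(tt, rt)
            kinds = [p.kind for p in a.pairs]
            paired = sum(k in (MATCH, PARTIAL, MISMATCH) for k in kinds)
            assert paired + kinds.count(RESPONSE_GAP) == len(t)
            assert paired + kinds.count(TARGET_GAP) == len(r)


@pytest.fixture(scope="module")
def scored(lexicon, table2_rows):
    out = {}
    for label, target, response, expected in table2_rows:
        trial = sp.TrialRecord("s1", "control", "1T", target, response)
        out[label] = (sp.score_trial(trial, lexicon), expected)
    return out


class TestScoreTrialEndToEnd:

    def test_worked_example_rows_reproduce_labels(self, scored):
        for label, (score, expected) in scored.items():
            assert score.dnh_status == expected["dnh"], label
            if expected["dnh"] != "none":
                assert score.content_errors is None
                assert score.function_errors is None
                assert score.morpheme_errors is None
            else:
                c, f = score.content_errors, score.function_errors
                assert (c.substitution, c.addition, c.omission) == expected["content"], label
                assert (f.substitution, f.addition, f.omission) == expected["function"], label
                assert score.morpheme_errors == expected["morphemes"], label

    def test_identity_response_is_error_free(self, lexicon):
        trial = sp.TrialRecord("s1", "control", "SSN",
                               "the DAUGHTER HELD the TABLE",
                               "the daughter held the table")
        s = sp.score_trial(trial, lexicon)
        assert s.keyword_correct == (True, True, True)
        assert s.dnh_status == "none"
        assert s.content_errors.total == 0
        assert s.function_errors.total == 0
        assert s.morpheme_errors == 0

    def test_empty_response_end_to_end(self, lexicon):
        trial = sp.TrialRecord("s1", "MDD", "1T", "the DAUGHTER HELD the TABLE", "")
        s = sp.score_trial(trial, lexicon)
        assert s.dnh_status == "dnh_nothing"
        assert s.keyword_correct == (False, False, False)
        assert s.content_errors is None and s.morpheme_errors is None

    def test_typo_corrected_before_scoring(self, lexicon):
        trial = sp.TrialRecord("s1", "control", "1T",
                               "a man is turning the FAUCET",
                               "a man is turning the facet")
        s = sp.score_trial(trial, lexicon)
        assert s.keyword_correct == (True,)
        assert s.content_errors.total == 0

    def test_masker_overlap_only_for_1t_dnh_incorrect(self, lexicon):
        inventory = frozenset({"go", "fast"})
        t = "the DAUGHTER SET the TABLE"
        r = "can go very fast"
        s_1t = sp.score_trial(sp.TrialRecord("s", "MDD", "1T", t, r),
                              lexicon, masker_roots=inventory)
        assert s_1t.dnh_status == "dnh_incorrect"
        assert s_1t.masker_overlap == (2, 3)  # go, fast matched; "very" not
        s_ssn = sp.score_trial(sp.TrialRecord("s", "MDD", "SSN", t, r),
                               lexicon, masker_roots=inventory)
        assert s_ssn.masker_overlap is None
        s_ok = sp.score_trial(sp.TrialRecord("s", "MDD", "1T", t,
                                             "the daughter set the table"),
                              lexicon, masker_roots=inventory)
        assert s_ok.masker_overlap is None

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            sp.TrialRecord("s", "MDD", "2T", "a B", "a b")
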