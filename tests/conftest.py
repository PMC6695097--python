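import pytest

import spinscore as sp


@pytest.fixture(scope="session")
def lexicon():
    return sp.default_lexicon()


def toks(sentence, lexicon):
    """Tag a plain (no-keyword) sentence into tokens."""
    return sp.tag_tokens(sentence.split(), lexicon)


# The nine worked-example rows: label, target, response, expected error
# profile once scored (counts are (substitution, addition, omission)).
TABLE2_ROWS = [
    ("dnh_nothing", "he broke his leg", "",
     dict(dnh="dnh_nothing")),
    ("dnh_incorrect", "the daughter set the table", "can go very fast",
     dict(dnh="dnh_incorrect")),
    ("omission_of_content_word", "a man is turning the faucet",
     "is turning the faucet",
     dict(dnh="none", content=(0, 0, 1), function=(0, 0, 1), morphemes=0)),
    ("omission_of_function_word", "a man is turning the faucet",
     "is turning the faucet",
     dict(dnh="none", content=(0, 0, 1), function=(0, 0, 1), morphemes=0)),
    ("addition_of_content_word", "a man is turning the faucet",
     "a man is turning the faucet trees",
     dict(dnh="none", content=(0, 1, 0), function=(0, 0, 0), morphemes=0)),
    ("addition_of_function_word", "father forgot the bread",
     "the father forgot the bread",
     dict(dnh="none", content=(0, 0, 0), function=(0, 1, 0), morphemes=0)),
    ("substitution_of_content_word", "the boy hurried to school",
     "the boy went to school",
     dict(dnh="none", content=(1, 0, 0), function=(0, 0, 0), morphemes=0)),
    ("substitution_of_function_word", "a man is turning the faucet",
     "the man is turning the faucet",
     dict(dnh="none", content=(0, 0, 0), function=(1, 0, 0), morphemes=0)),
    ("morpheme_error", "the daughter set the table",
     "the daughters set the table",
     dict(dnh="none", content=(0, 0, 0), function=(0, 0, 0), morphemes=1)),
]


@pytest.fixture(scope="session")
def table2_rows():
    return TABLE2_ROWS
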