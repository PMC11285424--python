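import math

import numpy as np
import pytest

from n400link import SimConfig, TableLM, bigram_lm_from_corpus, generate

TOY_CORPUS = [
    "the cat sat on the mat",
    "the dog sat on the rug",
    "a cat saw the dog",
    "the dog saw a cat",
    "a bird sat on the mat",
    "the bird saw the cat",
]


@pytest.fixture(scope="session")
def toy_corpus():
    return list(TOY_CORPUS)


@pytest.fixture(scope="session")
def bigram_lm(toy_corpus):
    return bigram_lm_from_corpus(toy_corpus)


@pytest.fixture()
def toy_table_lm():
    """Hand-built table backend over a 5-word vocabulary."""
    e1 = math.exp(-1.0)
    return TableLM("toy", {
        "": {"the": e1, "a": 1.0 - e1},
        "the": {"cat": 0.2, "dog": 0.5, "bird": 0.3},
        "the cat": {"sat": 0.5, "saw": 0.5},
        "big": {"cat": 0.5, "dog": 0.5},
    })


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study reused by read-mostly tests."""
    return generate(SimConfig(n_subjects=8, n_items=15, n_mock_lms=2), seed=7)


@pytest.fixture(scope="session")
def default_bundle():
    """One bundle at the default study conditions (30 subjects x 60 items)."""
    return generate(SimConfig(), seed=42)
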