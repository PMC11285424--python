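import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from n400link import (
    EXP_SUBLOG_SURPRISAL,
    PROBABILITY,
    SUBLOG_SURPRISAL,
    SURPRISAL,
    MetricSpec,
    WordScore,
    apply_metric,
    metric_table,
    word_surprisal,
    zscore,
)
from n400link.errors import (
    BackendContractError,
    DegenerateInputError,
    InvalidInputError,
    MetricOverflowError,
    MissingItemsError,
)

LN2 = math.log(2.0)


class _BadBackend:
    identifier = "bad"

    def tokenize(self, text):
        return text.split()

    def next_token_logprob(self, context, token):
        return 0.1  # impossible: probability > 1


def test_single_token_surprisal_is_negative_log_probability(toy_table_lm):
    score = word_surprisal(toy_table_lm, "", "the")
    assert score.surprisal == pytest.approx(1.0, abs=1e-12)
    assert score.probability == pytest.approx(math.exp(-1.0), abs=1e-15)
    assert score.token_count == 1


def test_multi_token_surprisal_is_sum_of_conditionals(toy_table_lm):
    """Two tokens with conditionals 0.2 and 0.5 give p = 0.1, S = ln 10."""
    score = word_surprisal(toy_table_lm, "the", "cat sat")
    assert score.probability == pytest.approx(0.1, abs=1e-12)
    assert score.surprisal == pytest.approx(-math.log(0.1), abs=1e-12)
    assert score.token_count == 2


@pytest.mark.parametrize("context,word", [
    ("", "the cat sat"),
    ("the", "cat saw the dog"),
    ("a", "bird sat on the mat"),
])
def test_bigram_surprisal_matches_hand_counted_product(bigram_lm, toy_corpus,
                                                       context, word):
    """Word surprisal equals -log of the product of count-based conditionals."""
    from collections import defaultdict
    counts = defaultdict(lambda: defaultdict(int))
    for sent in toy_corpus:
        toks = ["<s>"] + sent.split()
        for prev, nxt in zip(toks, toks[1:]):
            counts[prev][nxt] += 1
    prev = context.split()[-1] if context else "<s>"
    prob = 1.0
    for tok in word.split():
        prob *= counts[prev][tok] / sum(counts[prev].values())
        prev = tok
    score = word_surprisal(bigram_lm, context, word)
    assert score.surprisal == pytest.approx(-math.log(prob), abs=1e-12)


def test_empty_word_is_invalid(toy_table_lm):
    with pytest.raises(InvalidInputError, match="zero tokens"):
        word_surprisal(toy_table_lm, "the", "   ")


def test_positive_logprob_violates_backend_contract():
    with pytest.raises(BackendContractError):
        word_surprisal(_BadBackend(), "", "word")


def _score(s, base="natural"):
    p = math.exp(-s) if base == "natural" else 2.0 ** (-s)
    return WordScore("i", "lm", p, s, 1, base)


@pytest.mark.parametrize("s,k,expected", [
    (4.0, 0.5, 2.0),
    (2.0, -1.0, 0.5),
    (3.0, 1.0, 3.0),
])
def test_powered_surprisal_values(s, k, expected):
    assert apply_metric(_score(s), MetricSpec("powered_surprisal", k)) == \
        pytest.approx(expected, abs=1e-12)


def test_exponent_one_reproduces_surprisal_exactly():
    score = _score(2.302585092994046)
    assert apply_metric(score, SURPRISAL) == score.surprisal


def test_exp_powered_surprisal_matches_log_identity():
    # 8^0.6 = e^(0.6 ln 8): the two routes agree to double precision
    got = apply_metric(_score(8.0), EXP_SUBLOG_SURPRISAL)
    assert got == pytest.approx(math.exp(math.exp(0.6 * math.log(8.0))),
                                rel=1e-12)


def test_zero_surprisal_domain_errors():
    one = WordScore("i", "lm", 1.0, 0.0, 1)
    with pytest.raises(DegenerateInputError):
        apply_metric(one, MetricSpec("powered_surprisal", -1.0))
    with pytest.raises(DegenerateInputError):
        apply_metric(one, EXP_SUBLOG_SURPRISAL)
    # k > 0 is fine at S = 0
    assert apply_metric(one, SURPRISAL) == 0.0


def test_exp_metric_overflow_reports_item():
    # exponent 3 at S = 700 nats pushes e^(S^3) past double range
    with pytest.raises(MetricOverflowError) as err:
        apply_metric(_score(700.0), MetricSpec("exp_powered_surprisal", 3.0))
    assert "i" in err.value.items


def test_zscore_reference_values():
    np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0],
                               atol=1e-12)


def test_zscore_is_idempotent():
    z = zscore([0.3, -1.2, 2.4, 0.1, -0.9])
    np.testing.assert_allclose(zscore(z), z, atol=1e-10)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e3, 1e3, allow_subnormal=False),
                min_size=3, max_size=30, unique=True),
       st.floats(-100, 100), st.floats(0.01, 100))
def test_zscore_affine_invariance(values, a, b):
    x = np.asarray(values)
    assume(np.std(x) > 1e-3)
    np.testing.assert_allclose(zscore(a + b * x), zscore(x), atol=1e-8)


def test_zscore_rejects_constant_vector():
    with pytest.raises(DegenerateInputError):
        zscore([2.0, 2.0, 2.0])


@settings(derandomize=True, max_examples=40)
@given(st.floats(0.1, 20), st.floats(0.1, 20), st.floats(0.1, 3))
def test_powered_surprisal_monotone_in_surprisal(s1, s2, k):
    if s1 == s2:
        return
    lo, hi = sorted([s1, s2])
    inc = apply_metric(_score(hi), MetricSpec("powered_surprisal", k)) \
        - apply_metric(_score(lo), MetricSpec("powered_surprisal", k))
    dec = apply_metric(_score(hi), MetricSpec("powered_surprisal", -k)) \
        - apply_metric(_score(lo), MetricSpec("powered_surprisal", -k))
    assert inc > 0 and dec < 0


# -- metric_table ----------------------------------------------------------

STIM = pd.DataFrame({
    "item_id": ["i1", "i2", "i3"],
    "context": ["the", "the", ""],
    "critical_word": ["cat", "dog", "a"],
})


def test_metric_table_cardinality_and_consistency(toy_table_lm):
    specs = (PROBABILITY, SURPRISAL, SUBLOG_SURPRISAL)
    other = type(toy_table_lm)("toy2", {k: toy_table_lm.distribution(k)
                                        for k in toy_table_lm.contexts})
    table = metric_table([toy_table_lm, other], STIM, specs)
    assert len(table) == 3 * 2 * 3
    wide = table.pivot_table(index=["item_id", "lm_id"], columns="metric",
                             values="value")
    np.testing.assert_allclose(wide["S"], -np.log(wide["P"]), atol=1e-12)
    # identical backends give identical columns
    a = table[table.lm_id == "toy"].drop(columns="lm_id").reset_index(drop=True)
    b = table[table.lm_id == "toy2"].drop(columns="lm_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_metric_table_lists_unscorable_items(toy_table_lm):
    stim = pd.concat([STIM, pd.DataFrame({"item_id": ["i4"],
                                          "context": ["the mat"],
                                          "critical_word": ["zzz"]})],
                     ignore_index=True)
    with pytest.raises(MissingItemsError) as err:
        metric_table([toy_table_lm], stim, (SURPRISAL,))
    assert err.value.items == ["i4"]


def test_zscored_powered_surprisal_is_log_base_invariant(toy_table_lm):
    """z(S^k) is identical under natural and base-2 logs; e^(S^0.6) is not."""
    specs = (SUBLOG_SURPRISAL, SURPRISAL, EXP_SUBLOG_SURPRISAL)
    nat = metric_table([toy_table_lm], STIM, specs, log_base="natural")
    bits = metric_table([toy_table_lm], STIM, specs, log_base="base2")
    for name in ("S", "S^0.6"):
        np.testing.assert_allclose(
            nat.loc[nat.metric == name, "z_value"].to_numpy(),
            bits.loc[bits.metric == name, "z_value"].to_numpy(), atol=1e-10)
    e_nat = nat.loc[nat.metric == "e^(S^0.6)", "z_value"].to_numpy()
    e_bit = bits.loc[bits.metric == "e^(S^0.6)", "z_value"].to_numpy()
    assert np.max(np.abs(e_nat - e_bit)) > 1e-6


def test_multi_token_split_consistency(bigram_lm):
    """Summed token surprisals equal -log of the probability product for any split."""
    words = "cat sat on the mat"
    whole = word_surprisal(bigram_lm, "the", words)
    toks = words.split()
    for cut in range(1, len(toks)):
        first = word_surprisal(bigram_lm, "the", " ".join(toks[:cut]))
        rest = word_surprisal(bigram_lm, "the " + " ".join(toks[:cut]),
                              " ".join(toks[cut:]))
        assert first.surprisal + rest.surprisal == pytest.approx(
            whole.surprisal, abs=1e-12)
        assert whole.surprisal == pytest.approx(
            -math.log(first.probability * rest.probability), abs=1e-12)
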