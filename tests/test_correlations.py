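import numpy as np
import pytest

from n400link import (
    DictEmbedding,
    SimConfig,
    cloze_similarity_correlation,
    contextual_similarity,
    correlate_with_cloze,
    correlate_with_similarity,
    generate,
)
from n400link.correlations import normalize_context
from n400link.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
    ValidationError,
)

PROVIDER = DictEmbedding({
    "east": [1.0, 0.0],
    "north": [0.0, 1.0],
    "alias": [1.0, 0.0],
    "southish": [-1.0, -0.2],
})


def test_identical_vectors_have_similarity_one():
    assert contextual_similarity(PROVIDER, ["east"], "alias") == pytest.approx(1.0)


def test_orthogonal_vectors_have_similarity_zero():
    assert contextual_similarity(PROVIDER, ["east"], "north") == pytest.approx(
        0.0, abs=1e-15)


def test_two_context_words_mean_vector_case():
    # mean of (1,0) and (0,1) against (1,0): 0.5 / (sqrt(0.5) * 1) = sqrt(2)/2
    got = contextual_similarity(PROVIDER, ["east", "north"], "alias")
    assert got == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


def test_unembeddable_context_words_are_skipped():
    got = contextual_similarity(PROVIDER, ["zzz", "east"], "alias")
    assert got == pytest.approx(1.0)
    with pytest.raises(InvalidInputError, match="no embeddable"):
        contextual_similarity(PROVIDER, ["zzz"], "alias")
    with pytest.raises(InvalidInputError, match="not embeddable"):
        contextual_similarity(PROVIDER, ["east"], "zzz")


def test_zero_norm_mean_context_is_degenerate():
    provider = DictEmbedding({"a": [1.0, 0.0], "b": [-1.0, 0.0],
                              "w": [0.5, 0.5]})
    with pytest.raises(DegenerateInputError):
        contextual_similarity(provider, ["a", "b"], "w")


def test_embedding_table_validation():
    with pytest.raises(ValidationError):
        DictEmbedding({"a": [1.0, 0.0], "b": [0.0, 0.0]})   # zero vector
    with pytest.raises(ValidationError):
        DictEmbedding({"a": [1.0, 0.0], "b": [1.0, 0.0, 0.0]})  # mixed dims


def test_normalize_context_lowercases_and_strips_punctuation():
    assert normalize_context("The  cat, sat -- on THE mat!") == \
        ["the", "cat", "sat", "on", "the", "mat"]


# -- cloze correlations -------------------------------------------------------

def test_cloze_filter_is_strict():
    """Exactly the items with cloze > 0.05 survive; 0.05 itself is excluded."""
    cloze = np.array([0.01, 0.05, 0.06, 0.9, 0.5, 0.2])
    metric = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    row = correlate_with_cloze(cloze, metric)
    assert row.n_used == 4
    with pytest.raises(InsufficientDataError, match="2 item"):
        correlate_with_cloze(np.array([0.01, 0.05, 0.06, 0.9]),
                             np.array([1.0, 2.0, 3.0, 4.0]))


def test_affine_metric_of_cloze_correlates_perfectly():
    cloze = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    row = correlate_with_cloze(cloze, 2.0 - 3.0 * cloze)
    assert row.abs_r == pytest.approx(1.0, abs=1e-12)


def test_constant_metric_after_filter_is_degenerate():
    cloze = np.array([0.2, 0.4, 0.6, 0.01])
    with pytest.raises(DegenerateInputError):
        correlate_with_cloze(cloze, np.array([1.0, 1.0, 1.0, 9.0]))


def test_null_metric_rarely_correlates():
    """Independent metric vs cloze: |r| below 0.12 in at least 95% of draws."""
    rng = np.random.default_rng(17)
    n, hits, seeds = 500, 0, 100
    for _ in range(seeds):
        cloze = rng.uniform(0.06, 1.0, n)
        metric = rng.standard_normal(n)
        hits += correlate_with_cloze(cloze, metric).abs_r < 0.12
    assert hits / seeds >= 0.95


# -- similarity correlations --------------------------------------------------

def test_negated_similarity_correlates_perfectly():
    sims = np.array([0.1, -0.2, 0.5, 0.8, -0.6])
    row = correlate_with_similarity(sims, -sims)
    assert row.abs_r == pytest.approx(1.0, abs=1e-12)
    assert row.n_used == 5


def test_constant_similarity_is_degenerate():
    with pytest.raises(DegenerateInputError):
        correlate_with_similarity(np.full(5, 0.3), np.arange(5.0))


def test_generator_hits_designed_similarity_correlation():
    """corr(similarity, surprisal) matches the configured target."""
    bundle = generate(SimConfig(n_subjects=2, n_items=1000,
                                similarity_rho=0.5, n_mock_lms=1), seed=23)
    items = list(bundle.stimuli["item_id"])
    sims = np.array([bundle.similarities[i] for i in items])
    s_true = bundle.truth["s_true"]
    r = np.corrcoef(sims, s_true)[0, 1]
    assert r == pytest.approx(0.5, abs=1e-9)   # exact by construction
    # and the reported |r| against a mock LM's surprisal is close to 0.5
    s_lm = np.array([bundle.surprisals["lm00"][i] for i in items])
    row = correlate_with_similarity(sims, s_lm)
    assert row.abs_r == pytest.approx(0.5, abs=0.08)


def test_recomputed_similarities_match_bundle(small_bundle):
    """Cosine from the stored embeddings reproduces the designed values."""
    for rec in small_bundle.stimuli.itertuples(index=False):
        got = contextual_similarity(small_bundle.embeddings,
                                    normalize_context(rec.context),
                                    rec.critical_word)
        assert got == pytest.approx(small_bundle.similarities[rec.item_id],
                                    abs=1e-10)


def test_cloze_similarity_correlation_cases():
    cloze = np.array([0.1, 0.4, 0.7, 0.9])
    assert cloze_similarity_correlation(cloze, cloze) == pytest.approx(1.0)
    assert cloze_similarity_correlation(cloze, 1 - 2 * cloze) == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    r = cloze_similarity_correlation(rng.uniform(0, 1, 2000),
                                     rng.uniform(0, 1, 2000))
    assert r < 0.08
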