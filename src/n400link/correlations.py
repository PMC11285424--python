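"""Correlating the metric family with cloze and contextual similarity.

Two behavioral/ distributional targets stand in for what an LM metric might
be capturing:

* **cloze probability** — the proportion of norming participants producing
  the critical word; the subjective-predictability benchmark.  Following the
  norming convention, correlations are computed only over items with cloze
  strictly greater than 0.05 (low-cloze estimates are unreliable).
* **contextual similarity** — cosine similarity between the critical word's
  embedding and the unweighted mean embedding of the preceding context
  words; a proxy for semantic feature overlap with the context.

All correlations are reported as |Pearson r|: the metrics differ in sign
convention (probability falls, surprisal rises, with unexpectedness), and
only the strength of the association is compared.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
    ValidationError,
)

__all__ = [
    "EmbeddingProvider",
    "DictEmbedding",
    "CorrelationRow",
    "contextual_similarity",
    "correlate_with_cloze",
    "correlate_with_similarity",
    "cloze_similarity_correlation",
    "CLOZE_FILTER_THRESHOLD",
]

#: items at or below this cloze value are excluded from cloze correlations
CLOZE_FILTER_THRESHOLD = 0.05

_PUNCT = re.compile(r"[^\w'-]+")


class EmbeddingProvider:
    """Minimal word-embedding interface: deterministic ``vector(word)``."""

    identifier: str
    dimension: int

    def vector(self, word: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __contains__(self, word: str) -> bool:  # pragma: no cover - interface
        raise NotImplementedError


class DictEmbedding(EmbeddingProvider):
    """Table-driven embeddings, loadable from a JSON ``{word: vector}`` file."""

    def __init__(self, vectors: Mapping[str, Sequence[float]],
                 identifier: str = "mock-embeddings"):
        if not vectors:
            raise ValidationError("empty embedding table")
        self.identifier = identifier
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        dims = {v.shape for v in self._vectors.values()}
        if len(dims) != 1 or next(iter(dims))[0] < 2:
            raise ValidationError("embeddings must share one dimension >= 2")
        self.dimension = next(iter(dims))[0]
        for w, v in self._vectors.items():
            if not np.any(v):
                raise ValidationError(f"zero vector for word {w!r}")

    def vector(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    @classmethod
    def from_json(cls, path, identifier: Optional[str] = None) -> "DictEmbedding":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(payload, identifier=identifier or "mock-embeddings")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({w: [float(x) for x in v] for w, v in self._vectors.items()},
                      fh, sort_keys=True)


@dataclass
class CorrelationRow:
    """|Pearson r| between one metric and one target, with its sample size."""

    dataset: str
    lm_id: str
    metric: str
    target: str                      # "cloze" | "contextual_similarity"
    abs_r: float
    n_used: int


def normalize_context(context: str) -> list:
    """Whitespace-split, lowercase, punctuation-stripped context words."""
    words = []
    for tok in context.split():
        clean = _PUNCT.sub("", tok.lower()).strip("'-")
        if clean:
            words.append(clean)
    return words


def contextual_similarity(provider: EmbeddingProvider,
                          context_words: Sequence[str],
                          critical_word: str) -> float:
    """Cosine between the mean context embedding and the critical embedding.

    Context words absent from the provider are skipped (counted against the
    precondition that at least one remains).
    """
    if not context_words:
        raise InvalidInputError("no context words supplied")
    embeddable = [w for w in context_words if w in provider]
    if not embeddable:
        raise InvalidInputError("no embeddable context words")
    if critical_word not in provider:
        raise InvalidInputError(f"critical word {critical_word!r} not embeddable")
    mean_ctx = np.mean([provider.vector(w) for w in embeddable], axis=0)
    crit = provider.vector(critical_word)
    norm_c, norm_w = np.linalg.norm(mean_ctx), np.linalg.norm(crit)
    if norm_c == 0.0 or norm_w == 0.0:
        raise DegenerateInputError("zero-norm vector in cosine similarity")
    return float(np.dot(mean_ctx, crit) / (norm_c * norm_w))


def _abs_pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    if x.std(ddof=1) == 0.0 or y.std(ddof=1) == 0.0:
        raise DegenerateInputError(f"zero variance in {what}")
    return float(abs(stats.pearsonr(x, y).statistic))


def correlate_with_cloze(cloze: Sequence[float], metric_values: Sequence[float],
                         filter_threshold: float = CLOZE_FILTER_THRESHOLD,
                         dataset: str = "", lm_id: str = "",
                         metric: str = "") -> CorrelationRow:
    """|r| between a metric and cloze over items with cloze > threshold."""
    cloze = np.asarray(cloze, dtype=float)
    vals = np.asarray(metric_values, dtype=float)
    if cloze.shape != vals.shape:
        raise InvalidInputError("cloze and metric vectors differ in length")
    mask = cloze > filter_threshold       # strict inequality
    n_used = int(mask.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"only {n_used} item(s) with cloze > {filter_threshold}")
    r = _abs_pearson(cloze[mask], vals[mask], "cloze or metric after filtering")
    return CorrelationRow(dataset=dataset, lm_id=lm_id, metric=metric,
                          target="cloze", abs_r=r, n_used=n_used)


def correlate_with_similarity(similarities: Sequence[float],
                              metric_values: Sequence[float],
                              dataset: str = "", lm_id: str = "",
                              metric: str = "") -> CorrelationRow:
    """|r| between a metric and contextual similarity (no cloze filter)."""
    sims = np.asarray(similarities, dtype=float)
    vals = np.asarray(metric_values, dtype=float)
    if sims.shape != vals.shape:
        raise InvalidInputError("similarity and metric vectors differ in length")
    if sims.size < 3:
        raise InsufficientDataError(f"only {sims.size} item(s)")
    r = _abs_pearson(sims, vals, "similarity or metric")
    return CorrelationRow(dataset=dataset, lm_id=lm_id, metric=metric,
                          target="contextual_similarity", abs_r=r,
                          n_used=int(sims.size))


def cloze_similarity_correlation(cloze: Sequence[float],
                                 similarities: Sequence[float]) -> float:
    """Plain |r| between cloze probability and contextual similarity."""
    cloze = np.asarray(cloze, dtype=float)
    sims = np.asarray(similarities, dtype=float)
    if cloze.shape != sims.shape:
        raise InvalidInputError("cloze and similarity vectors differ in length")
    if cloze.size < 3:
        raise InsufficientDataError(f"only {cloze.size} item(s)")
    return _abs_pearson(cloze, sims, "cloze or similarity")
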