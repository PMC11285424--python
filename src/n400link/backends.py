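"""Conditional language-model scoring backends.

A backend is anything that can (a) tokenize text and (b) return the
log-probability of a token given the preceding token sequence.  Autoregressive
models are required: only they assign well-defined probabilities to words that
tokenize into several sub-word tokens (the product of the per-token
conditionals).

Two table-driven backends ship with the package:

* :class:`TableLM` — conditional distributions read from an explicit
  ``{context: {token: prob}}`` mapping (JSON-loadable), used as the mock
  backend throughout the test-suite and the pipeline.
* :class:`BigramLM` — a count-based bigram model estimated from a toy corpus.

Pretrained transformer adapters can be registered at run time via
:func:`register_backend`; none are bundled.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from typing import Callable, Dict, List, Protocol, Sequence, runtime_checkable

from .errors import BackendContractError, ValidationError

__all__ = [
    "ConditionalLM",
    "TableLM",
    "BigramLM",
    "bigram_lm_from_corpus",
    "register_backend",
    "get_backend_factory",
    "BACKEND_REGISTRY",
]

_SUM_TOL = 1e-6


@runtime_checkable
class ConditionalLM(Protocol):
    """Contract for an autoregressive scoring backend.

    ``next_token_logprob`` must be deterministic and return a natural-log
    probability ``<= 0``; for any fixed context the exponentiated values over
    the vocabulary must sum to one.
    """

    identifier: str

    def tokenize(self, text: str) -> List[str]: ...

    def next_token_logprob(self, context: Sequence[str], token: str) -> float: ...


class TableLM:
    """Mock conditional LM backed by an explicit distribution table.

    Parameters
    ----------
    identifier : str
        Name recorded in every :class:`~n400link.metrics.WordScore`.
    table : dict
        ``{context_key: {token: probability}}`` where ``context_key`` is the
        space-joined context token sequence (``""`` for the empty context).
        Every distribution must sum to one within ``1e-6``.
    """

    def __init__(self, identifier: str, table: Dict[str, Dict[str, float]]):
        self.identifier = identifier
        self._table = {k: dict(v) for k, v in table.items()}
        self._validate()

    def _validate(self) -> None:
        for ctx, dist in self._table.items():
            if not dist:
                raise ValidationError(f"empty distribution for context {ctx!r}")
            total = math.fsum(dist.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValidationError(
                    f"distribution for context {ctx!r} sums to {total!r}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"negative probability under context {ctx!r}")

    # -- ConditionalLM contract -------------------------------------------
    def tokenize(self, text: str) -> List[str]:
        return text.split()

    def next_token_logprob(self, context: Sequence[str], token: str) -> float:
        key = " ".join(context)
        try:
            dist = self._table[key]
        except KeyError:
            raise LookupError(
                f"backend {self.identifier!r}: no distribution for context {key!r}"
            ) from None
        try:
            p = dist[token]
        except KeyError:
            raise LookupError(
                f"backend {self.identifier!r}: token {token!r} not in "
                f"distribution for context {key!r}"
            ) from None
        if p <= 0:
            raise BackendContractError(
                f"backend {self.identifier!r}: zero probability for {token!r}"
            )
        return math.log(p)

    # -- conveniences ------------------------------------------------------
    @property
    def contexts(self) -> List[str]:
        return list(self._table)

    def distribution(self, context_key: str) -> Dict[str, float]:
        return dict(self._table[context_key])

    @property
    def vocabulary(self) -> List[str]:
        vocab = set()
        for dist in self._table.values():
            vocab.update(dist)
        return sorted(vocab)

    @classmethod
    def from_json(cls, path, identifier: str | None = None) -> "TableLM":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if "table" in payload:  # {"identifier": ..., "table": {...}}
            return cls(identifier or payload.get("identifier", "mock-table"),
                       payload["table"])
        return cls(identifier or "mock-table", payload)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"identifier": self.identifier, "table": self._table},
                      fh, indent=1, sort_keys=True)


class BigramLM:
    """Count-based bigram model over a whitespace-tokenized corpus.

    Each sentence is padded with a start symbol; the conditional distribution
    of the next token depends only on the immediately preceding token
    (maximum-likelihood estimates, no smoothing, so only attested bigrams are
    scorable).
    """

    START = "<s>"

    def __init__(self, identifier: str, counts: Dict[str, Dict[str, int]]):
        self.identifier = identifier
        self._counts = counts
        self._totals = {prev: sum(nxt.values()) for prev, nxt in counts.items()}

    def tokenize(self, text: str) -> List[str]:
        return text.split()

    def next_token_logprob(self, context: Sequence[str], token: str) -> float:
        prev = context[-1] if context else self.START
        if prev not in self._counts or token not in self._counts[prev]:
            raise LookupError(
                f"backend {self.identifier!r}: unattested bigram ({prev!r}, {token!r})"
            )
        return math.log(self._counts[prev][token] / self._totals[prev])


def bigram_lm_from_corpus(sentences: Sequence[str],
                          identifier: str = "bigram") -> BigramLM:
    """Estimate a :class:`BigramLM` from an iterable of sentences."""
    counts: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sent in sentences:
        tokens = [BigramLM.START] + sent.split()
        for prev, nxt in zip(tokens, tokens[1:]):
            counts[prev][nxt] += 1
    return BigramLM(identifier, {k: dict(v) for k, v in counts.items()})


# -- backend registry ------------------------------------------------------

BACKEND_REGISTRY: Dict[str, Callable[..., ConditionalLM]] = {}


def register_backend(name: str, factory: Callable[..., ConditionalLM]) -> None:
    """Register a named backend factory (e.g. a pretrained-model adapter)."""
    BACKEND_REGISTRY[name] = factory


def get_backend_factory(name: str) -> Callable[..., ConditionalLM]:
    try:
        return BACKEND_REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"no backend named {name!r}; registered: {sorted(BACKEND_REGISTRY)}"
        ) from None


register_backend("mock-table", TableLM.from_json)
register_backend("bigram", bigram_lm_from_corpus)
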