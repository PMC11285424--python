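"""Word-level probability metrics and their power-transform family.

The quantity of interest for every critical word is its contextual
probability ``p`` under an autoregressive LM, summarized either directly or
through surprisal ``S = -log p`` and its transforms:

* ``P``          — probability itself,
* ``S^k``        — powered surprisal (``k = 1`` is plain surprisal; ``k < 1``
  sub-logarithmic, ``k > 1`` super-logarithmic),
* ``e^(S^0.6)``  — the exponentiated sub-logarithmic metric.

Multi-token words are handled by the product rule: each sub-word token is
scored given the context plus the preceding tokens of the word, and the
per-token surprisals are summed (equivalently, probabilities multiplied).

All metrics destined for a regression are z-scored within
(LM, metric, dataset); because ``(c*S)^k = c^k * S^k``, z-scored powered
surprisal does not depend on the logarithm base, while ``e^(S^0.6)`` does —
the base is therefore recorded on every :class:`WordScore`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .backends import ConditionalLM
from .errors import (
    BackendContractError,
    DegenerateInputError,
    InvalidInputError,
    MetricOverflowError,
    MissingItemsError,
)

__all__ = [
    "WordScore",
    "MetricSpec",
    "PROBABILITY",
    "SURPRISAL",
    "SUBLOG_SURPRISAL",
    "EXP_SUBLOG_SURPRISAL",
    "DEFAULT_SPECS",
    "word_surprisal",
    "apply_metric",
    "zscore",
    "metric_table",
]

_LN2 = math.log(2.0)
# exp() overflows above ~709.78 in double precision
_EXP_MAX_ARG = math.log(np.finfo(float).max)


@dataclass(frozen=True)
class WordScore:
    """Probability and surprisal of one critical word under one backend."""

    item_id: str
    lm_id: str
    probability: float
    surprisal: float
    token_count: int
    log_base: str = "natural"  # "natural" | "base2"

    def __post_init__(self):
        if not (0.0 < self.probability <= 1.0):
            raise InvalidInputError(
                f"probability {self.probability!r} outside (0, 1] for "
                f"item {self.item_id!r}"
            )
        if self.log_base not in ("natural", "base2"):
            raise InvalidInputError(f"unknown log base {self.log_base!r}")
        expected = -math.log(self.probability)
        if self.log_base == "base2":
            expected /= _LN2
        if abs(self.surprisal - expected) > 1e-12 * max(1.0, abs(expected)):
            raise InvalidInputError(
                f"surprisal {self.surprisal!r} inconsistent with probability "
                f"{self.probability!r} in base {self.log_base!r}"
            )


@dataclass(frozen=True)
class MetricSpec:
    """One member of the metric family.

    ``exponent`` is ignored for ``probability`` and fixed at 0.6 by default
    for ``exp_powered_surprisal``.
    """

    kind: str
    exponent: float | None = None

    _KINDS = ("probability", "powered_surprisal", "exp_powered_surprisal")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise InvalidInputError(f"unknown metric kind {self.kind!r}")
        if self.kind == "powered_surprisal":
            if self.exponent is None or not math.isfinite(self.exponent):
                raise InvalidInputError("powered_surprisal requires a finite exponent")
        if self.kind == "exp_powered_surprisal" and self.exponent is None:
            object.__setattr__(self, "exponent", 0.6)

    @property
    def name(self) -> str:
        if self.kind == "probability":
            return "P"
        if self.kind == "powered_surprisal":
            return "S" if self.exponent == 1 else f"S^{self.exponent:g}"
        return f"e^(S^{self.exponent:g})"


PROBABILITY = MetricSpec("probability")
SURPRISAL = MetricSpec("powered_surprisal", 1.0)
SUBLOG_SURPRISAL = MetricSpec("powered_surprisal", 0.6)
EXP_SUBLOG_SURPRISAL = MetricSpec("exp_powered_surprisal", 0.6)
#: the four metrics compared against cloze and contextual similarity
DEFAULT_SPECS = (PROBABILITY, SURPRISAL, SUBLOG_SURPRISAL, EXP_SUBLOG_SURPRISAL)


def word_surprisal(lm: ConditionalLM, context: str, word: str,
                   log_base: str = "natural", item_id: str = "") -> WordScore:
    """Score one word in context under an autoregressive backend.

    The word's tokens are scored left to right, each conditioned on the
    context tokens plus the word tokens already scored; the per-token
    surprisals are summed.
    """
    if log_base not in ("natural", "base2"):
        raise InvalidInputError(f"unknown log base {log_base!r}")
    word_tokens = lm.tokenize(word)
    if not word_tokens:
        raise InvalidInputError(f"word {word!r} yields zero tokens under {lm.identifier!r}")
    running: List[str] = list(lm.tokenize(context)) if context else []
    total_nats = 0.0
    for tok in word_tokens:
        lp = lm.next_token_logprob(tuple(running), tok)
        if not math.isfinite(lp) or lp > 0.0:
            raise BackendContractError(
                f"backend {lm.identifier!r} returned log-probability {lp!r} "
                f"for token {tok!r}"
            )
        total_nats -= lp
        running.append(tok)
    surprisal = total_nats / _LN2 if log_base == "base2" else total_nats
    return WordScore(
        item_id=item_id,
        lm_id=lm.identifier,
        probability=math.exp(-total_nats),
        surprisal=surprisal,
        token_count=len(word_tokens),
        log_base=log_base,
    )


def apply_metric(score: WordScore, spec: MetricSpec) -> float:
    """Evaluate one metric for one scored word."""
    if spec.kind == "probability":
        return score.probability
    s = score.surprisal
    if spec.kind == "powered_surprisal":
        k = float(spec.exponent)
        if s == 0.0 and k <= 0.0:
            raise DegenerateInputError(
                f"item {score.item_id!r}: S=0 with exponent {k} is undefined"
            )
        return float(s ** k)
    # exp_powered_surprisal
    if s <= 0.0:
        raise DegenerateInputError(
            f"item {score.item_id!r}: e^(S^{spec.exponent:g}) requires S > 0"
        )
    arg = s ** float(spec.exponent)
    if arg > _EXP_MAX_ARG:
        raise MetricOverflowError([score.item_id])
    return float(math.exp(arg))


def zscore(values: Union[Sequence[float], np.ndarray, pd.Series]) -> np.ndarray:
    """Standardize to mean 0, sample (ddof=1) standard deviation 1."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError("zscore expects a 1-D vector")
    if arr.size < 2:
        raise InvalidInputError("zscore requires at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("zscore requires finite values")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("constant vector cannot be z-scored")
    return (arr - arr.mean()) / sd


def metric_table(lms: Iterable[ConditionalLM],
                 stimuli: pd.DataFrame,
                 specs: Sequence[MetricSpec] = DEFAULT_SPECS,
                 log_base: str = "natural") -> pd.DataFrame:
    """Long table of raw and z-scored metric values.

    Parameters
    ----------
    lms : iterable of backends
    stimuli : DataFrame with columns ``item_id``, ``context``, ``critical_word``
    specs : metric family members to evaluate

    Returns
    -------
    DataFrame with one row per (item, lm, spec) and columns
    ``item_id, lm_id, metric, value, z_value``; z-scoring is within
    (lm, metric) over the stimulus set.
    """
    required = {"item_id", "context", "critical_word"}
    missing_cols = required - set(stimuli.columns)
    if missing_cols:
        raise InvalidInputError(f"stimuli table lacks columns {sorted(missing_cols)}")

    rows = []
    for lm in lms:
        failed: List[str] = []
        scores: Dict[str, WordScore] = {}
        for rec in stimuli.itertuples(index=False):
            try:
                scores[rec.item_id] = word_surprisal(
                    lm, rec.context, rec.critical_word,
                    log_base=log_base, item_id=rec.item_id)
            except LookupError:
                failed.append(rec.item_id)
        if failed:
            raise MissingItemsError(
                failed, f"backend {lm.identifier!r} cannot score items {failed}")
        for spec in specs:
            values = np.array([apply_metric(scores[i], spec)
                               for i in stimuli["item_id"]])
            z = zscore(values)
            for item, raw, zv in zip(stimuli["item_id"], values, z):
                rows.append((item, lm.identifier, spec.name, raw, zv))
    return pd.DataFrame(rows, columns=["item_id", "lm_id", "metric",
                                       "value", "z_value"])
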