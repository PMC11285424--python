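"""Synthetic trial-level N400 bundles with known ground truth.

The generator is a generative mirror of the regression models the package
fits.  One bundle contains everything a full analysis run consumes:

* **items** — each carries a true surprisal drawn log-uniformly on
  [0.5, 12] nats (so probabilities span several orders of magnitude, as
  sentence-final critical words do), plus item-level covariates.
* **trials** — fully crossed subjects × items;
  ``amplitude = beta0 + beta_metric * z(link) + beta_baseline * z(baseline)
  + sum beta_cov * z(cov) + lab offset + subject effect + item effect +
  residual``, with the link being ``S^k_true`` (or raw probability).
* **mock language models** — each LM reports the true item log-probability
  perturbed by Gaussian noise, mimicking a family of imperfect models of
  the same distribution.
* **cloze** — a noisy monotone (inverse-logit) transform of ``S^0.6``,
  clipped to [0, 1].
* **embeddings** — per-item context/critical vectors constructed so the
  cosine similarity sequence has an exact target sample correlation with
  true surprisal.

Identical config + seed reproduces every table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .backends import TableLM
from .correlations import DictEmbedding
from .data import Dataset, preset_recipe
from .errors import InvalidInputError
from .metrics import zscore

__all__ = ["SimConfig", "SimBundle", "generate", "mock_lm_from_table",
           "write_bundle"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the package's study conditions."""

    # link between item probability and amplitude
    link: str = "powered_surprisal"          # or "probability"
    k_true: float = 0.6
    # fixed effects (microvolts per SD of the z-scored predictor)
    beta0: float = 0.0
    beta_metric: float = -3.0
    beta_baseline: float = 0.3
    beta_covariates: Mapping[str, float] = field(default_factory=lambda: {
        "concreteness": 0.2, "log_frequency": -0.2,
        "old20": 0.15, "sentence_position": 0.1})
    # variance components (microvolts)
    sd_subject: float = 1.0
    sd_item: float = 0.25
    sd_residual: float = 1.5
    # design size
    n_subjects: int = 30
    n_items: int = 60
    n_labs: int = 3
    lab_offset_sd: float = 0.4
    # item probability law: log-uniform surprisal (nats)
    surprisal_range: Tuple[float, float] = (0.5, 12.0)
    # mock language models
    n_mock_lms: int = 5
    lm_noise_sd: float = 0.1                 # on the log-probability scale
    # cloze link: logit(cloze) = 2 - 1.2 * S^0.6 + noise
    cloze_noise_sd: float = 0.6
    # embeddings
    embedding_dim: int = 8
    similarity_rho: float = -0.5             # target corr(similarity, S)
    seed: int = 0

    def validate(self) -> None:
        if self.link not in ("powered_surprisal", "probability"):
            raise InvalidInputError(f"unknown link {self.link!r}")
        for name in ("sd_subject", "sd_item", "sd_residual", "lm_noise_sd",
                     "cloze_noise_sd", "lab_offset_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.n_subjects * self.n_items < 20:
            raise InvalidInputError(
                "design too small: n_subjects * n_items must be >= 20")
        if self.n_labs < 1:
            raise InvalidInputError("n_labs must be >= 1")
        lo, hi = self.surprisal_range
        if not (0 < lo < hi):
            raise InvalidInputError("surprisal_range must satisfy 0 < lo < hi")
        if not (-1 < self.similarity_rho < 1):
            raise InvalidInputError("similarity_rho must lie in (-1, 1)")
        if self.embedding_dim < 2:
            raise InvalidInputError("embedding_dim must be >= 2")
        if self.n_mock_lms < 1:
            raise InvalidInputError("n_mock_lms must be >= 1")


@dataclass
class SimBundle:
    """One synthetic study: data, mock models, embeddings, and the truth."""

    dataset: Dataset
    stimuli: pd.DataFrame                     # item_id, context, critical_word, cloze
    surprisals: Dict[str, Dict[str, float]]  # lm_id -> {item_id: S (nats)}
    embeddings: DictEmbedding
    similarities: Dict[str, float]           # item_id -> cosine similarity
    config: SimConfig
    truth: Dict[str, np.ndarray]             # generating effects, for tests

    @property
    def lm_ids(self):
        return sorted(self.surprisals)

    def metric_values(self, lm_id: str) -> Dict[str, Dict[str, float]]:
        """P, S, S^0.6 and e^(S^0.6) item-level values for one mock LM."""
        return self._metric_family(self.surprisals[lm_id])

    def true_metric_values(self) -> Dict[str, Dict[str, float]]:
        """The metric family under the *generating* probabilities.

        Mock-LM metrics observe the item probabilities with noise, so a
        model already containing the generating link still gains a little
        from other transforms of a noisy LM's values.  Exact-null checks
        (e.g. type-I calibration of the partition battery) therefore need
        the noise-free metric table.
        """
        items = list(self.stimuli["item_id"])
        s_true = self.truth["s_true"]
        return self._metric_family(
            {i: float(v) for i, v in zip(items, s_true)})

    @staticmethod
    def _metric_family(s: Dict[str, float]) -> Dict[str, Dict[str, float]]:
        return {
            "P": {i: float(np.exp(-v)) for i, v in s.items()},
            "S": dict(s),
            "S^0.6": {i: float(v ** 0.6) for i, v in s.items()},
            "e^(S^0.6)": {i: float(np.exp(v ** 0.6)) for i, v in s.items()},
        }


def _orthonormal_noise(rng: np.random.Generator, anchor: np.ndarray) -> np.ndarray:
    """Unit-variance noise with exactly zero sample correlation to anchor."""
    n = anchor.size
    za = (anchor - anchor.mean())
    za /= np.linalg.norm(za)
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= (e @ za) * za
    norm = np.linalg.norm(e)
    if norm == 0:
        raise InvalidInputError("degenerate noise draw; use more items")
    return e / norm


def generate(config: SimConfig, seed: Optional[int] = None) -> SimBundle:
    """Draw one complete synthetic bundle (deterministic in config + seed)."""
    config.validate()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    n_items, n_subj = config.n_items, config.n_subjects

    item_ids = [f"item{i:04d}" for i in range(n_items)]
    subj_ids = [f"subj{j:03d}" for j in range(n_subj)]

    # -- items -------------------------------------------------------------
    lo, hi = config.surprisal_range
    s_true = np.exp(rng.uniform(np.log(lo), np.log(hi), n_items))
    covariates = {name: rng.standard_normal(n_items)
                  for name in sorted(config.beta_covariates)}

    # -- crossed design ------------------------------------------------------
    subj_idx = np.repeat(np.arange(n_subj), n_items)
    item_idx = np.tile(np.arange(n_items), n_subj)
    n_trials = n_subj * n_items

    link_item = (np.exp(-s_true) if config.link == "probability"
                 else s_true ** config.k_true)
    b_subj = rng.normal(0.0, config.sd_subject, n_subj)
    b_item = rng.normal(0.0, config.sd_item, n_items)
    lab_offsets = rng.normal(0.0, config.lab_offset_sd, config.n_labs)
    lab_of_subj = np.arange(n_subj) % config.n_labs     # round-robin
    baseline = rng.standard_normal(n_trials)
    resid = rng.normal(0.0, config.sd_residual, n_trials)

    # z-scoring at the trial level matches what the fitted designs see
    amplitude = (config.beta0
                 + config.beta_metric * zscore(link_item[item_idx])
                 + config.beta_baseline * zscore(baseline)
                 + lab_offsets[lab_of_subj[subj_idx]]
                 + b_subj[subj_idx] + b_item[item_idx] + resid)
    for name in sorted(config.beta_covariates):
        amplitude = amplitude + (config.beta_covariates[name]
                                 * zscore(covariates[name][item_idx]))

    trials = pd.DataFrame({
        "subject_id": np.array(subj_ids, dtype=object)[subj_idx],
        "item_id": np.array(item_ids, dtype=object)[item_idx],
        "lab": np.array([f"lab{l}" for l in range(config.n_labs)],
                        dtype=object)[lab_of_subj[subj_idx]],
        "amplitude": amplitude,
        "baseline": baseline,
        "concreteness": covariates.get("concreteness", np.zeros(n_items))[item_idx],
        "log_frequency": covariates.get("log_frequency", np.zeros(n_items))[item_idx],
        "old20": covariates.get("old20", np.zeros(n_items))[item_idx],
        "sentence_position": covariates.get("sentence_position",
                                            np.zeros(n_items))[item_idx],
    })

    # -- mock language models ------------------------------------------------
    surprisals: Dict[str, Dict[str, float]] = {}
    for m in range(config.n_mock_lms):
        noisy = s_true + rng.normal(0.0, config.lm_noise_sd, n_items)
        noisy = np.clip(noisy, 0.05, None)    # keep p strictly inside (0, 1)
        surprisals[f"lm{m:02d}"] = {i: float(v)
                                    for i, v in zip(item_ids, noisy)}

    # -- cloze ---------------------------------------------------------------
    s06 = s_true ** 0.6
    cloze = expit(2.0 - 1.2 * s06 + rng.normal(0.0, config.cloze_noise_sd, n_items))
    cloze = np.clip(cloze, 0.0, 1.0)

    # -- embeddings with exact target similarity-surprisal correlation -------
    rho = config.similarity_rho
    zs = (s_true - s_true.mean()) / np.linalg.norm(s_true - s_true.mean())
    noise = _orthonormal_noise(rng, s_true)
    sim_raw = rho * zs + np.sqrt(1.0 - rho ** 2) * noise
    sims = sim_raw * (0.95 / np.max(np.abs(sim_raw)))   # linear: r preserved

    dim = config.embedding_dim
    vectors: Dict[str, np.ndarray] = {}
    for i, item in enumerate(item_ids):
        u = rng.standard_normal(dim)
        u /= np.linalg.norm(u)
        w = rng.standard_normal(dim)
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        vectors[f"ctx{i:04d}"] = u
        vectors[f"word{i:04d}"] = sims[i] * u + np.sqrt(1.0 - sims[i] ** 2) * w

    stimuli = pd.DataFrame({
        "item_id": item_ids,
        "context": [f"ctx{i:04d}" for i in range(n_items)],
        "critical_word": [f"word{i:04d}" for i in range(n_items)],
        "cloze": cloze,
    })

    dataset = Dataset(name=f"synthetic-seed{config.seed}", trials=trials,
                      recipe=preset_recipe("lab_random_subject"),
                      stimuli=stimuli)
    return SimBundle(
        dataset=dataset,
        stimuli=stimuli,
        surprisals=surprisals,
        embeddings=DictEmbedding({w: v.tolist() for w, v in vectors.items()},
                                 identifier="mock-embeddings"),
        similarities={item: float(s) for item, s in zip(item_ids, sims)},
        config=config,
        truth={"s_true": s_true, "b_subj": b_subj, "b_item": b_item,
               "resid": resid, "lab_offsets": lab_offsets,
               "link_item": link_item},
    )


def mock_lm_from_table(path) -> TableLM:
    """Load a table-driven mock LM from JSON, validating normalization."""
    return TableLM.from_json(path)


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write a bundle in the same plain-text formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.dataset.trials.to_csv(outdir / "trials.csv", index=False)
    bundle.stimuli.to_csv(outdir / "stimuli.tsv", sep="\t", index=False)
    for lm_id in bundle.lm_ids:
        df = pd.DataFrame({
            "item_id": sorted(bundle.surprisals[lm_id]),
            "surprisal": [bundle.surprisals[lm_id][i]
                          for i in sorted(bundle.surprisals[lm_id])],
        })
        df.to_csv(outdir / f"surprisal_{lm_id}.csv", index=False)
    bundle.embeddings.to_json(outdir / "embeddings.json")
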