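"""End-to-end orchestration of the four analyses.

* Analysis 1 — exponent sweep + smoothed estimate of the best power of
  surprisal per dataset (and pooled across datasets).
* Analysis 2 — pairwise AIC contrasts between probability, surprisal and
  surprisal^0.6 across language models, with companion LRTs.
* Analysis 3 — the eight-test variance-partitioning battery per
  (dataset, LM).
* Analysis 4 — |Pearson r| of each metric against cloze (items with
  cloze > 0.05 only) and against embedding-based contextual similarity.

One Benjamini–Yekutieli family is applied per invocation across *all*
p-values the run emits (contrast LRTs plus the partition battery); the
family membership is written next to the results so alternative groupings
can be audited.  With fixed seed and mock backends a run is byte-identical
across invocations.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .correlations import (
    DictEmbedding,
    contextual_similarity,
    cloze_similarity_correlation,
    correlate_with_cloze,
    correlate_with_similarity,
    normalize_context,
)
from .data import Dataset, build_design, preset_recipe
from .errors import ConfigError, InsufficientDataError
from .link import (
    DEFAULT_GRID,
    AicSurface,
    ExponentEstimate,
    MetricContrast,
    estimate_k,
    metric_contrasts,
    sweep_exponents,
)
from .mixedlm import LrtResult, by_fdr, fit_lmm, lrt_table, variance_partition
from .simulate import SimBundle, SimConfig, generate, write_bundle

__all__ = [
    "run_analysis1",
    "run_analysis2_3",
    "run_analysis4",
    "run_all",
    "read_bundle",
]

_CONTRAST_METRICS = ("P", "S", "S^0.6")
_A4_METRICS = ("P", "S", "S^0.6", "e^(S^0.6)")


def _as_bundles(bundles) -> List[SimBundle]:
    return [bundles] if isinstance(bundles, SimBundle) else list(bundles)


def run_analysis1(bundles, grid: Sequence[float] = DEFAULT_GRID,
                  outdir: Optional[Union[str, Path]] = None,
                  ) -> Tuple[Dict[str, Tuple[AicSurface, ExponentEstimate]],
                             Optional[ExponentEstimate]]:
    """Sweep the exponent grid and estimate the best power per dataset.

    Returns ``({dataset: (surface, estimate)}, pooled_estimate)``; the
    pooled estimate (one global curve, per-dataset and per-LM offsets) is
    computed when more than one bundle is supplied.
    """
    bundles = _as_bundles(bundles)
    if not len(list(grid)):
        raise ConfigError("empty exponent grid")
    results: Dict[str, Tuple[AicSurface, ExponentEstimate]] = {}
    for bundle in bundles:
        surface = sweep_exponents(bundle.dataset, bundle.surprisals, grid=grid)
        est = estimate_k(surface)
        results[bundle.dataset.name] = (surface, est)
    pooled = (estimate_k([s for s, _ in results.values()], pooled=True)
              if len(results) > 1 else None)

    if outdir is not None:
        outdir = Path(outdir)
        for name, (surface, est) in sorted(results.items()):
            d = outdir / name / "analysis1"
            d.mkdir(parents=True, exist_ok=True)
            surface.to_csv(d / "aic_surface.csv")
            est.curve.to_csv(d / "dummy_lm_curve.csv", index=False)
            (d / "estimate.json").write_text(
                json.dumps(est.to_dict(), sort_keys=True, indent=1))
        if pooled is not None:
            d = outdir / "pooled" / "analysis1"
            d.mkdir(parents=True, exist_ok=True)
            (d / "estimate.json").write_text(
                json.dumps(pooled.to_dict(), sort_keys=True, indent=1))
    return results, pooled


def _metric_aic_table(bundle: SimBundle) -> pd.DataFrame:
    """AIC of the recipe fitted with each of P, S, S^0.6, per mock LM."""
    base = build_design(bundle.dataset,
                        bundle.metric_values(bundle.lm_ids[0])["S"])
    rows = []
    for lm_id in bundle.lm_ids:
        values = bundle.metric_values(lm_id)
        for metric in _CONTRAST_METRICS:
            fit = fit_lmm(base.with_metric(values[metric]),
                          label=f"{lm_id}:{metric}")
            rows.append((lm_id, metric, fit.aic))
    return pd.DataFrame(rows, columns=["lm_id", "metric", "aic"])


def run_analysis2_3(bundle: SimBundle,
                    outdir: Optional[Union[str, Path]] = None,
                    alpha: float = 0.05,
                    partition_recipe=None,
                    ) -> Tuple[List[MetricContrast], List[LrtResult]]:
    """Metric contrasts plus the variance-partitioning battery, one FDR family.

    The battery defaults to the ``baseline_covariates`` recipe: its item
    random effects are required for nested tests of item-level predictors to
    be calibrated (without them, unmodelled between-item variance inflates
    the chi-square statistics), and the synthetic bundles carry baseline and
    covariates by construction.
    """
    aic_table = _metric_aic_table(bundle)
    contrasts = metric_contrasts(aic_table, dataset_name=bundle.dataset.name)

    partition_recipe = partition_recipe or preset_recipe("baseline_covariates")
    battery: List[LrtResult] = []
    for lm_id in bundle.lm_ids:
        battery.extend(variance_partition(
            bundle.dataset, bundle.metric_values(lm_id),
            recipe=partition_recipe, apply_fdr=False, lm_id=lm_id))

    family: List[LrtResult] = [c.lrt for c in contrasts if c.lrt is not None]
    family += battery
    if family:
        adjusted = by_fdr([r.p_raw for r in family])
        for r, p in zip(family, adjusted):
            r.p_adjusted = float(p)

    if outdir is not None:
        d = Path(outdir) / bundle.dataset.name / "analysis2_3"
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(c.dataset_name, c.label, c.delta_aic, c.substantial, c.n_lms,
              c.lrt.chi2 if c.lrt else float("nan"),
              c.lrt.p_raw if c.lrt else float("nan"),
              c.lrt.p_adjusted if c.lrt else float("nan"))
             for c in contrasts],
            columns=["dataset", "contrast", "delta_aic", "substantial",
                     "n_lms", "chi2", "p_raw", "p_adjusted"],
        ).to_csv(d / "metric_contrasts.csv", index=False)
        lrt_table(battery).to_csv(d / "variance_partition.csv", index=False)
        (d / "fdr_family.json").write_text(json.dumps(
            {"method": "benjamini-yekutieli", "alpha": alpha,
             "tests": [f"{r.lm_id + ':' if r.lm_id else ''}{r.label}"
                       for r in family]},
            sort_keys=True, indent=1))
    return contrasts, battery


def run_analysis4(bundle: SimBundle,
                  outdir: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Correlations of each metric with cloze and contextual similarity.

    Yields ``n_lms * len(metrics) * 2 + 1`` rows per dataset: the extra row
    is the cloze–similarity correlation itself (lm_id and metric empty).
    """
    stim = bundle.stimuli
    sims = np.array([
        contextual_similarity(bundle.embeddings,
                              normalize_context(ctx), str(word).lower())
        for ctx, word in zip(stim["context"], stim["critical_word"])])
    cloze = stim["cloze"].to_numpy(dtype=float)
    items = list(stim["item_id"])

    rows = []
    name = bundle.dataset.name
    for lm_id in bundle.lm_ids:
        values = bundle.metric_values(lm_id)
        for metric in _A4_METRICS:
            vec = np.array([values[metric][i] for i in items])
            row = correlate_with_cloze(cloze, vec, dataset=name,
                                       lm_id=lm_id, metric=metric)
            rows.append((name, lm_id, metric, row.target, row.abs_r, row.n_used))
            row = correlate_with_similarity(sims, vec, dataset=name,
                                            lm_id=lm_id, metric=metric)
            rows.append((name, lm_id, metric, row.target, row.abs_r, row.n_used))
    rows.append((name, "", "", "cloze_vs_similarity",
                 cloze_similarity_correlation(cloze, sims), len(items)))
    table = pd.DataFrame(rows, columns=["dataset", "lm_id", "metric",
                                        "target", "abs_r", "n_used"])
    if outdir is not None:
        d = Path(outdir) / name / "analysis4"
        d.mkdir(parents=True, exist_ok=True)
        table.to_csv(d / "correlations.csv", index=False)
    return table


def run_all(outdir: Union[str, Path], seed: int = 0,
            config: Optional[SimConfig] = None,
            grid: Sequence[float] = DEFAULT_GRID) -> dict:
    """Simulate one bundle and run Analyses 1–4, writing all outputs.

    Returns a JSON-serializable summary (also written to ``summary.json``).
    """
    config = config or SimConfig()
    bundle = generate(config, seed=seed)
    outdir = Path(outdir)
    write_bundle(bundle, outdir / bundle.dataset.name / "bundle")

    a1, _ = run_analysis1(bundle, grid=grid, outdir=outdir)
    contrasts, battery = run_analysis2_3(bundle, outdir=outdir)
    correlations = run_analysis4(bundle, outdir=outdir)

    name = bundle.dataset.name
    surface, est = a1[name]
    summary = {
        "dataset": name,
        "seed": int(seed),
        "n_trials": int(bundle.dataset.n_trials),
        "n_lms": len(bundle.lm_ids),
        "k_true": (config.k_true if config.link == "powered_surprisal" else None),
        "k_hat": est.k_hat,
        "k_boundary": est.boundary,
        "fit_quality": round(est.fit_quality, 6),
        "contrasts": {c.label: {"delta_aic": round(c.delta_aic, 4),
                                "substantial": c.substantial}
                      for c in contrasts},
        "partition_significant": {
            f"{r.lm_id}:{r.label}": bool(r.significant())
            for r in battery},
        "correlation_rows": int(len(correlations)),
    }
    (outdir / name / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1))
    return summary


def read_bundle(bundle_dir: Union[str, Path],
                config: Optional[SimConfig] = None) -> SimBundle:
    """Reload a bundle written by :func:`~n400link.simulate.write_bundle`."""
    bundle_dir = Path(bundle_dir)
    trials = pd.read_csv(bundle_dir / "trials.csv")
    stimuli = pd.read_csv(bundle_dir / "stimuli.tsv", sep="\t")
    for col in ("item_id",):
        stimuli[col] = stimuli[col].astype(str)
    surprisals = {}
    for path in sorted(bundle_dir.glob("surprisal_*.csv")):
        lm_id = path.stem.replace("surprisal_", "")
        df = pd.read_csv(path)
        surprisals[lm_id] = dict(zip(df["item_id"].astype(str),
                                     df["surprisal"].astype(float)))
    if not surprisals:
        raise ConfigError(f"no surprisal tables found in {bundle_dir}")
    embeddings = DictEmbedding.from_json(bundle_dir / "embeddings.json")
    dataset = Dataset(name=bundle_dir.parent.name or bundle_dir.name,
                      trials=trials, recipe=preset_recipe("lab_random_subject"),
                      stimuli=stimuli)
    sims = {}
    for rec in stimuli.itertuples(index=False):
        try:
            sims[rec.item_id] = contextual_similarity(
                embeddings, normalize_context(rec.context),
                str(rec.critical_word).lower())
        except Exception:
            pass
    return SimBundle(dataset=dataset, stimuli=stimuli, surprisals=surprisals,
                     embeddings=embeddings, similarities=sims,
                     config=config or SimConfig(), truth={})
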