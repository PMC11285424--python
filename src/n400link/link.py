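"""Estimating the exponent of the probability–N400 link.

The question: which power ``k`` of surprisal, ``S^k``, best predicts N400
amplitude?  ``k = 1`` is the logarithmic (plain surprisal) link, ``k < 1``
sub-logarithmic, ``k > 1`` super-logarithmic.  The procedure:

1. :func:`sweep_exponents` — fit the dataset's regression recipe once per
   (language model, grid exponent), collecting the regression AIC into an
   :class:`AicSurface`.  The default grid is every 0.1 step in [0.1, 2.0]
   plus {-1, -0.5, -0.1} for comparison.
2. :class:`ExponentLinkEstimator` — smooth AIC over ``k`` with a penalized
   spline plus per-LM offsets, predict the population curve for a held-out
   dummy LM on the 0–2 grid, and report the argmin ``k_hat``.
3. :func:`metric_contrasts` — for the named metrics P, S and S^0.6, estimate
   pairwise AIC differences with a mixed model of AIC on metric (random
   intercept per LM); a |ΔAIC| of 4 or more counts as a substantial
   difference in fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import Dataset, ModelFrame, RandomStructure, build_design
from .errors import (
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
    InvalidInputError,
)
from .mixedlm import LmmFit, LrtResult, fit_lmm, likelihood_ratio
from .smoothing import PenalizedBSplineGAM

__all__ = [
    "DEFAULT_GRID",
    "PREDICTION_GRID",
    "AicSurface",
    "ExponentEstimate",
    "ExponentLinkEstimator",
    "MetricContrast",
    "sweep_exponents",
    "estimate_k",
    "metric_contrasts",
    "SUBSTANTIAL_DELTA_AIC",
]

#: exponent grid: all 0.1 increments in [0.1, 2] plus negative comparisons
DEFAULT_GRID: Tuple[float, ...] = tuple(
    [-1.0, -0.5, -0.1] + [round(0.1 * i, 1) for i in range(1, 21)])

#: dummy-LM prediction grid: 0 to 2 in 0.1 steps
PREDICTION_GRID: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(21))

#: conventional threshold for a substantial AIC difference
SUBSTANTIAL_DELTA_AIC = 4.0


@dataclass
class AicSurface:
    """Regression AIC as a function of exponent, per language model."""

    dataset_name: str
    table: pd.DataFrame              # columns lm_id, k, aic (NaN for failures)
    grid: Tuple[float, ...]
    failures: List[Tuple[str, float, str]] = field(default_factory=list)

    @property
    def n_lms(self) -> int:
        return self.table["lm_id"].nunique()

    @property
    def unreliable(self) -> bool:
        return len(self.failures) > 0.10 * len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ExponentEstimate:
    """Smoothed best exponent for one dataset (or pooled across datasets)."""

    k_hat: float
    boundary: bool
    fit_quality: float
    pooled: bool
    n_lms: int
    grid: Tuple[float, ...]
    curve: pd.DataFrame              # columns k, aic_pred

    def to_dict(self) -> dict:
        return {"k_hat": self.k_hat, "boundary": self.boundary,
                "fit_quality": round(self.fit_quality, 6),
                "pooled": self.pooled, "n_lms": self.n_lms,
                "grid": list(self.grid)}


def sweep_exponents(dataset: Dataset,
                    lm_surprisals: Mapping[str, Mapping[str, float]],
                    grid: Sequence[float] = DEFAULT_GRID,
                    recipe=None) -> AicSurface:
    """Fit the recipe for every (LM, exponent) cell and collect AICs.

    ``lm_surprisals`` maps each LM id to its item-level surprisal values
    (natural log).  The design is assembled once and only the z-scored
    metric column is swapped per cell, so every cell sees the identical
    response and random structure.
    """
    if not isinstance(lm_surprisals, Mapping):
        pairs = list(lm_surprisals)
        lm_ids = [lm for lm, _ in pairs]
        if len(lm_ids) != len(set(lm_ids)):
            raise InvalidInputError("duplicate LM ids in surprisal tables")
        lm_surprisals = dict(pairs)
    lm_ids = list(lm_surprisals)
    if not len(grid):
        raise InvalidInputError("empty exponent grid")

    base_lm = lm_ids[0]
    base_frame = build_design(dataset, lm_surprisals[base_lm], recipe=recipe)

    rows = []
    failures: List[Tuple[str, float, str]] = []
    for lm_id in lm_ids:
        s = pd.Series(dict(lm_surprisals[lm_id]), dtype=float)
        if (s <= 0).any():
            bad = sorted(s.index[s <= 0])
            raise InvalidInputError(
                f"LM {lm_id!r}: non-positive surprisal for items {bad[:10]}")
        for k in grid:
            try:
                frame = base_frame.with_metric((s ** k).to_dict())
                aic = fit_lmm(frame, label=f"{lm_id}:k={k}").aic
            except Exception as err:  # recorded, not fatal
                failures.append((lm_id, float(k), str(err)))
                aic = float("nan")
            rows.append((lm_id, float(k), aic))
    table = pd.DataFrame(rows, columns=["lm_id", "k", "aic"])
    surface = AicSurface(dataset_name=dataset.name, table=table,
                         grid=tuple(grid), failures=failures)
    if surface.unreliable:
        warnings.warn(
            f"{dataset.name}: {len(failures)} of {len(table)} sweep cells "
            "failed; surface marked unreliable", stacklevel=2)
    return surface


class ExponentLinkEstimator(BaseEstimator):
    """Estimate the best-fitting exponent from an AIC surface.

    ``fit`` expects a long table with columns ``k``, ``aic`` and ``lm_id``
    (plus ``dataset`` when ``pooled=True``).  The AIC values are smoothed
    with :class:`PenalizedBSplineGAM` using per-LM offset terms (and
    per-dataset offsets in pooled mode); the population-level prediction —
    offsets averaged out, the "dummy LM" — is evaluated on the 0–2 grid and
    its argmin reported as ``k_hat_``.

    Attributes (after fit): ``k_hat_``, ``boundary_``, ``fit_quality_``,
    ``curve_``, ``n_lms_``.
    """

    def __init__(self, pooled: bool = False, n_splines: int = 10,
                 lambdas=None, prediction_grid: Sequence[float] = PREDICTION_GRID):
        self.pooled = pooled
        self.n_splines = n_splines
        self.lambdas = lambdas
        self.prediction_grid = prediction_grid

    def fit(self, aic_table: pd.DataFrame, y=None):
        df = aic_table.dropna(subset=["aic"]).copy()
        n_lms = df["lm_id"].nunique() if len(df) else 0
        if n_lms < 2:
            raise InsufficientDataError(
                f"need >=2 language models with valid AICs, got {n_lms}")
        if df["k"].nunique() < 5:
            raise InsufficientDataError(
                f"need >=5 grid points with valid AICs, got {df['k'].nunique()}")
        if np.ptp(df["aic"].to_numpy()) == 0:
            raise DegenerateInputError("all AIC values are equal")

        if self.pooled and "dataset" in df.columns and df["dataset"].nunique() > 1:
            groups = df[["lm_id", "dataset"]].to_numpy(dtype=object)
        else:
            groups = df["lm_id"].to_numpy(dtype=object)

        gam = PenalizedBSplineGAM(n_splines=self.n_splines, lambdas=self.lambdas)
        gam.fit(df["k"].to_numpy(dtype=float), df["aic"].to_numpy(dtype=float),
                groups=groups)
        grid = np.asarray(self.prediction_grid, dtype=float)
        pred = gam.predict(grid)
        idx = int(np.argmin(pred))

        self.gam_ = gam
        self.n_lms_ = int(n_lms)
        self.k_hat_ = float(grid[idx])
        self.boundary_ = bool(idx == 0 or idx == len(grid) - 1)
        self.fit_quality_ = float(gam.adj_r2_)
        self.curve_ = pd.DataFrame({"k": grid, "aic_pred": pred})
        return self

    def estimate(self) -> ExponentEstimate:
        return ExponentEstimate(
            k_hat=self.k_hat_, boundary=self.boundary_,
            fit_quality=self.fit_quality_, pooled=self.pooled,
            n_lms=self.n_lms_, grid=tuple(float(k) for k in self.prediction_grid),
            curve=self.curve_)


def estimate_k(surface, pooled: bool = False, **kwargs) -> ExponentEstimate:
    """Smoothed best exponent for one surface or a list of surfaces."""
    if isinstance(surface, AicSurface):
        table = surface.table.assign(dataset=surface.dataset_name)
    else:  # sequence of surfaces -> pooled table
        table = pd.concat([s.table.assign(dataset=s.dataset_name)
                           for s in surface], ignore_index=True)
    est = ExponentLinkEstimator(pooled=pooled, **kwargs)
    est.fit(table)
    return est.estimate()


# ---------------------------------------------------------------------------
# metric contrasts (P vs S vs S^0.6)


@dataclass
class MetricContrast:
    """Estimated AIC difference between two metrics across language models."""

    metric_a: str
    metric_b: str
    delta_aic: float                 # a minus b; positive = b fits better
    substantial: bool
    n_lms: int
    lrt: Optional[LrtResult] = None
    dataset_name: str = ""

    @property
    def label(self) -> str:
        return f"{self.metric_a}-{self.metric_b}"


_DEFAULT_PAIRS = (("P", "S"), ("P", "S^0.6"), ("S", "S^0.6"))


def _aic_meta_model(sub: pd.DataFrame, pair: Tuple[str, str],
                    dataset_name: str) -> Tuple[float, Optional[LrtResult]]:
    """Mixed model of AIC on metric with a per-LM random intercept."""
    a, b = pair
    codes, levels = pd.factorize(sub["lm_id"], sort=True)
    rs = RandomStructure(factor="lm_id", codes=np.asarray(codes),
                         levels=[str(l) for l in levels])
    y = sub["aic"].to_numpy(dtype=float)
    X_full = pd.DataFrame({
        "Intercept": np.ones(len(sub)),
        "metric_a": (sub["metric"] == a).astype(float).to_numpy(),
    })
    data = sub.reset_index(drop=True)
    frame = ModelFrame(y=y, X=X_full, random=[rs], data=data,
                       dataset_name=dataset_name)
    full = fit_lmm(frame, label=f"aic~metric ({a} vs {b})")
    null = fit_lmm(frame.subset([]), label=f"aic~1 ({a} vs {b})")
    lrt = likelihood_ratio(null, full, df=1, label=f"{a}-{b}")
    return float(full.fixed_estimates["metric_a"]), lrt


def metric_contrasts(aic_table: pd.DataFrame,
                     pairs: Sequence[Tuple[str, str]] = _DEFAULT_PAIRS,
                     dataset_name: str = "") -> List[MetricContrast]:
    """Pairwise metric comparison from a complete (LM × metric) AIC table.

    ``aic_table`` needs columns ``lm_id``, ``metric``, ``aic``.  In a
    balanced complete table the mixed-model estimate equals the mean paired
    AIC difference.  Each contrast carries a companion LRT of whether metric
    predicts AIC at all.
    """
    required = {"lm_id", "metric", "aic"}
    if not required <= set(aic_table.columns):
        raise InvalidInputError(f"AIC table needs columns {sorted(required)}")
    metrics_needed = sorted({m for pair in pairs for m in pair})
    cells = aic_table.groupby(["lm_id", "metric"]).size()
    lms = sorted(aic_table["lm_id"].unique())
    missing = [(lm, m) for lm in lms for m in metrics_needed
               if (lm, m) not in cells.index]
    if missing:
        raise InvalidInputError(f"missing AIC cells: {missing}")

    out: List[MetricContrast] = []
    for a, b in pairs:
        sub = aic_table[aic_table["metric"].isin([a, b])].copy()
        if len(lms) == 1:
            delta = float(sub.loc[sub["metric"] == a, "aic"].mean()
                          - sub.loc[sub["metric"] == b, "aic"].mean())
            lrt = None
        else:
            delta, lrt = _aic_meta_model(sub, (a, b), dataset_name)
        out.append(MetricContrast(
            metric_a=a, metric_b=b, delta_aic=delta,
            # epsilon guards the exact-boundary case against solver round-off
            substantial=bool(abs(delta) >= SUBSTANTIAL_DELTA_AIC - 1e-9),
            n_lms=len(lms), lrt=lrt, dataset_name=dataset_name))
    return out
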