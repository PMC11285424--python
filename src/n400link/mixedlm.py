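"""Maximum-likelihood linear mixed models, LRTs and Benjamini–Yekutieli FDR.

All models are fitted by maximum likelihood (never REML): the whole point of
the engine is to compare AIC and run likelihood-ratio tests across models
that differ in their *fixed* effects, and those comparisons are only valid
under ML.

Two fitting routes share one result type:

* a profiled-likelihood path for the single-random-intercept structure
  (the multi-lab recipe and the AIC-on-metric meta-models).  The marginal
  likelihood of ``y = X b + Z u + e`` with one intercept per group has a
  closed form; profiling out ``b`` and the residual variance leaves a 1-D
  optimization over the variance ratio, which is fast and deterministic —
  the exponent sweep fits thousands of these models;
* ``statsmodels`` ``MixedLM`` for every other structure (random slopes,
  crossed subject/item components).

``n_params`` counts fixed coefficients + distinct variance/covariance
parameters + the residual variance, so ``AIC = 2 n_params - 2 logLik`` is
reproducible across engines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .data import Dataset, ModelFrame, RandomStructure, build_design
from .errors import (
    DesignError,
    InvalidInputError,
    NotNestedError,
    RankDeficiencyError,
)

__all__ = [
    "LmmFit",
    "LrtResult",
    "fit_lmm",
    "likelihood_ratio",
    "variance_partition",
    "PARTITION_BATTERY",
    "by_fdr",
]

_SINGULAR_TOL = 1e-6


@dataclass
class LmmFit:
    """One fitted mixed model (maximum likelihood)."""

    logLik: float
    n_params: int
    fixed_estimates: Dict[str, float]
    variance_estimates: Dict[str, float]
    converged: bool
    singular: bool
    n_obs: int
    random_signature: str
    method: str
    dataset_name: str = ""
    label: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.logLik

    @property
    def deviance(self) -> float:
        return -2.0 * self.logLik

    @property
    def fixed_names(self) -> Tuple[str, ...]:
        return tuple(self.fixed_estimates)


@dataclass
class LrtResult:
    """One nested-model likelihood-ratio test, labelled "base + added"."""

    label: str
    chi2: float
    df: int
    p_raw: float
    p_adjusted: float = float("nan")
    dataset_name: str = ""
    lm_id: str = ""

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted <= alpha


# ---------------------------------------------------------------------------
# fitting


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"fixed design is rank {rank} with {X.shape[1]} columns {list(names)}")


def _fit_random_intercept_ml(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                             n_groups: int) -> Tuple[float, np.ndarray, float, float]:
    """Profiled ML for a single random-intercept model.

    Returns (logLik, beta, sigma2_resid, sigma2_group).  The variance ratio
    lam = sigma2_group / sigma2_resid is optimized on the log scale; beta and
    the residual variance have closed forms given lam (Woodbury identity on
    the block-compound-symmetric marginal covariance).
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)
    ni = np.bincount(codes, minlength=n_groups).astype(float)

    def components(lam: float):
        c = lam / (1.0 + lam * ni)
        XtVX = XtX - (Sx * c[:, None]).T @ Sx
        XtVy = Xty - Sx.T @ (c * Sy)
        ytVy = yty - float(np.sum(c * Sy ** 2))
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        rss = max(ytVy - float(XtVy @ beta), 1e-300)
        return beta, rss

    def negll(loglam: float) -> float:
        lam = math.exp(loglam)
        try:
            _, rss = components(lam)
        except linalg.LinAlgError:
            return 1e300
        sigma2 = rss / n
        logdet = float(np.sum(np.log1p(lam * ni)))
        return 0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)

    res = optimize.minimize_scalar(negll, bounds=(-30.0, 15.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    # compare against the boundary lam -> 0 (plain OLS)
    candidates = [(negll(res.x), res.x), (negll(-60.0), -60.0)]
    best_nll, best_loglam = min(candidates, key=lambda t: t[0])
    lam = math.exp(best_loglam)
    beta, rss = components(lam)
    sigma2 = rss / n
    return -best_nll, beta, sigma2, lam * sigma2


def _vc_design(frame: ModelFrame) -> Tuple[np.ndarray, List[Tuple[str, slice]]]:
    """Dense random-effect design with one column block per variance component.

    Components (factor intercepts, factor slopes) are independent; columns
    within a block share one variance."""
    blocks: List[np.ndarray] = []
    names: List[Tuple[str, slice]] = []
    start = 0
    for rs in frame.random:
        ind = np.zeros((frame.n_obs, rs.n_levels))
        ind[np.arange(frame.n_obs), rs.codes] = 1.0
        if rs.intercept:
            blocks.append(ind)
            names.append((f"{rs.factor}:Intercept",
                          slice(start, start + rs.n_levels)))
            start += rs.n_levels
        for s in rs.slopes:
            x = frame.data[s].to_numpy(dtype=float)
            blocks.append(ind * x[:, None])
            names.append((f"{rs.factor}:{s}", slice(start, start + rs.n_levels)))
            start += rs.n_levels
    return np.column_stack(blocks), names


def _fit_vc_ml(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
               components: List[Tuple[str, slice]]
               ) -> Tuple[float, np.ndarray, float, np.ndarray, bool]:
    """Profiled ML for independent variance components (crossed factors).

    The marginal covariance is ``sigma2 * (I + Z D Z')`` with ``D`` diagonal,
    one ratio per component.  beta and sigma2 have closed forms given the
    ratios (Woodbury on the q-dimensional inner matrix), leaving a smooth
    optimization over the log-ratios.
    """
    n, p = X.shape
    q = Z.shape[1]
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_c = len(components)

    def pieces(loglams: np.ndarray):
        d = np.empty(q)
        for lam, (_, sl) in zip(np.exp(loglams), components):
            d[sl.start:sl.stop] = lam
        rd = np.sqrt(d)
        M = np.eye(q) + (rd[:, None] * ZtZ) * rd[None, :]
        R = linalg.cholesky(M, lower=True)
        W = linalg.solve_triangular(R, rd[:, None] * ZtX, lower=True)
        wy = linalg.solve_triangular(R, rd * Zty, lower=True)
        XtVX = XtX - W.T @ W
        XtVy = Xty - W.T @ wy
        ytVy = yty - float(wy @ wy)
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        rss = max(ytVy - float(XtVy @ beta), 1e-300)
        logdet = 2.0 * float(np.sum(np.log(np.diag(R))))
        return beta, rss, logdet

    def negll(loglams: np.ndarray) -> float:
        try:
            _, rss, logdet = pieces(loglams)
        except linalg.LinAlgError:
            return 1e300
        sigma2 = rss / n
        return 0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)

    starts = [np.full(n_c, math.log(0.2)), np.full(n_c, math.log(1e-3))]
    best = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                bounds=[(-25.0, 10.0)] * n_c,
                                options={"ftol": 1e-12, "gtol": 1e-9,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    beta, rss, _ = pieces(best.x)
    sigma2 = rss / n
    lams = np.exp(best.x)
    singular = bool(np.any(lams < 1e-7))
    return -best.fun, beta, sigma2, lams * sigma2, singular


def _fit_statsmodels(frame: ModelFrame) -> Tuple[object, int, Dict[str, float], bool]:
    """Fit via statsmodels MixedLM; returns (result, n_vparams, variances, singular)."""
    y, X = frame.y, frame.X.to_numpy(dtype=float)
    names = list(frame.X.columns)
    if len(frame.random) == 1:
        rs = frame.random[0]
        cols = ([np.ones(frame.n_obs)] if rs.intercept else [])
        re_names = (["Intercept"] if rs.intercept else [])
        for s in rs.slopes:
            cols.append(frame.data[s].to_numpy(dtype=float))
            re_names.append(s)
        exog_re = np.column_stack(cols)
        model = MixedLM(y, X, groups=rs.codes, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=False, maxiter=500)
        q = exog_re.shape[1]
        n_vparams = q * (q + 1) // 2 + 1
        cov = np.atleast_2d(np.asarray(result.cov_re)) * result.scale
        variances = {f"{rs.factor}:{nm}": float(cov[i, i])
                     for i, nm in enumerate(re_names)}
        variances["residual"] = float(result.scale)
        eigs = np.linalg.eigvalsh(cov)
        singular = bool(eigs.min() < _SINGULAR_TOL * max(eigs.max(), 1e-12))
    else:
        # crossed factors as independent variance components, one super-group
        df = frame.data.copy()
        df["_y"] = y
        for i, nm in enumerate(names):
            df[f"_x{i}"] = X[:, i]
        df["_all"] = 1
        vc: Dict[str, str] = {}
        for rs in frame.random:
            if rs.intercept:
                vc[f"{rs.factor}"] = f"0 + C({rs.factor})"
            for s in rs.slopes:
                vc[f"{rs.factor}_{s}"] = f"0 + C({rs.factor}):{s}"
        fixed = " + ".join(f"_x{i}" for i in range(len(names)))
        model = MixedLM.from_formula(f"_y ~ 0 + {fixed}", groups="_all",
                                     vc_formula=vc, re_formula="0", data=df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # lbfgs handles the variance-component profile far better than
            # the default optimizer here; the reverse holds for exog_re
            result = model.fit(reml=False, method="lbfgs", maxiter=500)
        n_vparams = len(vc) + 1
        vcomp = np.asarray(result.vcomp, dtype=float) * result.scale
        variances = {nm: float(v) for nm, v in zip(sorted(vc), vcomp)}
        variances["residual"] = float(result.scale)
        singular = bool(len(vcomp) and
                        vcomp.min() < _SINGULAR_TOL * max(vcomp.max(), 1e-12))
    return result, n_vparams, variances, singular


def fit_lmm(frame: ModelFrame, label: str = "", method: str = "auto") -> LmmFit:
    """Fit one linear mixed model by maximum likelihood.

    ``method`` selects the route: ``"auto"`` uses the profiled 1-D path for a
    single random intercept, statsmodels for a single factor with correlated
    slope+intercept, and the variance-components path for crossed factors;
    ``"vc"`` or ``"statsmodels"`` force a route (used for cross-validation of
    the engines against each other).

    Raises :class:`RankDeficiencyError` for a rank-deficient fixed design;
    non-convergence and singular random-effect estimates are flagged on the
    result, not raised.
    """
    X = frame.X.to_numpy(dtype=float)
    names = list(frame.X.columns)
    if not frame.random:
        raise DesignError("no random structure; use OLS for fixed-only models")
    for rs in frame.random:
        if rs.n_levels < 2:
            raise DesignError(f"grouping factor {rs.factor!r} has <2 levels")
    _check_full_rank(X, names)

    single_ri = (len(frame.random) == 1 and frame.random[0].intercept
                 and not frame.random[0].slopes)
    if single_ri and method in ("auto", "profiled"):
        rs = frame.random[0]
        ll, beta, s2e, s2b = _fit_random_intercept_ml(
            frame.y, X, rs.codes, rs.n_levels)
        return LmmFit(
            logLik=float(ll),
            n_params=X.shape[1] + 2,
            fixed_estimates=dict(zip(names, map(float, beta))),
            variance_estimates={f"{rs.factor}:Intercept": float(s2b),
                                "residual": float(s2e)},
            converged=True,
            singular=bool(s2b < _SINGULAR_TOL * max(s2e, 1e-12)),
            n_obs=frame.n_obs,
            random_signature=frame.random_signature(),
            method="profiled-ri",
            dataset_name=frame.dataset_name,
            label=label,
        )

    single_correlated = (len(frame.random) == 1 and frame.random[0].slopes
                         and frame.random[0].intercept)
    use_statsmodels = (method == "statsmodels"
                       or (method == "auto" and single_correlated))
    if not use_statsmodels:
        Z, components = _vc_design(frame)
        ll, beta, s2e, s2c, singular = _fit_vc_ml(
            frame.y, X, Z, components)
        variances = {nm: float(v) for (nm, _), v in zip(components, s2c)}
        variances["residual"] = float(s2e)
        return LmmFit(
            logLik=float(ll),
            n_params=X.shape[1] + len(components) + 1,
            fixed_estimates=dict(zip(names, map(float, beta))),
            variance_estimates=variances,
            converged=True,
            singular=singular,
            n_obs=frame.n_obs,
            random_signature=frame.random_signature(),
            method="profiled-vc",
            dataset_name=frame.dataset_name,
            label=label,
        )

    result, n_vparams, variances, singular = _fit_statsmodels(frame)
    if not result.converged:
        warnings.warn(f"mixed model {label or frame.dataset_name!r} did not "
                      "converge; result flagged", stacklevel=2)
    fe = {nm: float(b) for nm, b in zip(names, np.asarray(result.fe_params))}
    return LmmFit(
        logLik=float(result.llf),
        n_params=X.shape[1] + n_vparams,
        fixed_estimates=fe,
        variance_estimates=variances,
        converged=bool(result.converged),
        singular=singular,
        n_obs=frame.n_obs,
        random_signature=frame.random_signature(),
        method="statsmodels-mixedlm",
        dataset_name=frame.dataset_name,
        label=label,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests


def likelihood_ratio(base: LmmFit, augmented: LmmFit, df: int,
                     label: str = "") -> LrtResult:
    """Chi-square LRT of ``augmented`` against the nested ``base`` model."""
    if df < 1:
        raise InvalidInputError("df must be >= 1")
    if base.n_obs != augmented.n_obs:
        raise NotNestedError("models were fitted to different responses")
    if base.random_signature != augmented.random_signature:
        raise NotNestedError("models have different random structures")
    if not set(base.fixed_names) <= set(augmented.fixed_names):
        raise NotNestedError(
            f"fixed terms {set(base.fixed_names) - set(augmented.fixed_names)} "
            "of the base model are absent from the augmented model")
    chi2 = 2.0 * (augmented.logLik - base.logLik)
    if chi2 < -1e-6:
        warnings.warn(
            f"LRT {label!r}: augmented logLik below base by {-chi2 / 2:.3g} "
            "(optimizer failure); statistic clipped to 0", stacklevel=2)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LrtResult(label=label, chi2=float(chi2), df=df, p_raw=p,
                     dataset_name=base.dataset_name)


#: the variance-partitioning battery, in report order: (label, base, added)
PARTITION_BATTERY: Tuple[Tuple[str, Tuple[str, ...], Tuple[str, ...]], ...] = (
    ("S^0.6 + S",         ("S^0.6",),         ("S",)),
    ("S^0.6 + P",         ("S^0.6",),         ("P",)),
    ("S + S^0.6",         ("S",),             ("S^0.6",)),
    ("S + P",             ("S",),             ("P",)),
    ("P + S",             ("P",),             ("S",)),
    ("P + S^0.6",         ("P",),             ("S^0.6",)),
    ("(S + P) + S^0.6",   ("S", "P"),         ("S^0.6",)),
    ("S^0.6 + (S + P)",   ("S^0.6",),         ("S", "P")),
)


def variance_partition(dataset: Dataset,
                       metrics: Mapping[str, Mapping[str, float]],
                       recipe=None,
                       apply_fdr: bool = True,
                       lm_id: str = "") -> List[LrtResult]:
    """Run the eight-test battery asking which metrics explain unique variance.

    ``metrics`` maps the three metric names ``P``, ``S`` and ``S^0.6`` to
    item-level value mappings.  Every model in the battery is fitted against
    the identical response and random structure, so the tests are valid
    nested comparisons.  Labels follow the "base + added" convention, e.g.
    ``"S + P"`` tests whether probability explains variance beyond surprisal.
    """
    needed = {"P", "S", "S^0.6"}
    if set(metrics) < needed:
        raise InvalidInputError(f"metrics must include {sorted(needed)}")

    extra = {name: metrics[name] for name in ("S", "S^0.6")}
    full = build_design(dataset, metrics["P"], recipe=recipe,
                        extra_metrics=extra)
    full.X = full.X.rename(columns={"metric": "P"})

    fits: Dict[Tuple[str, ...], LmmFit] = {}

    def fit_subset(terms: Tuple[str, ...]) -> LmmFit:
        key = tuple(sorted(terms))
        if key not in fits:
            other = [c for c in full.X.columns
                     if c != "Intercept" and c not in needed]
            try:
                fits[key] = fit_lmm(full.subset(list(terms) + other),
                                    label="+".join(terms))
            except DesignError as err:
                raise type(err)(f"model {{{' + '.join(terms)}}}: {err}") from err
        return fits[key]

    results: List[LrtResult] = []
    for lbl, base_terms, added_terms in PARTITION_BATTERY:
        try:
            base = fit_subset(base_terms)
            augm = fit_subset(base_terms + added_terms)
        except DesignError as err:
            raise type(err)(f"test {lbl!r}: {err}") from err
        res = likelihood_ratio(base, augm, df=len(added_terms), label=lbl)
        res.lm_id = lm_id
        res.dataset_name = dataset.name
        results.append(res)

    if apply_fdr:
        adjusted = by_fdr([r.p_raw for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = float(p_adj)
    return results


def lrt_table(results: Sequence[LrtResult]) -> pd.DataFrame:
    """Serialize LRT results to a flat table."""
    return pd.DataFrame(
        [(r.dataset_name, r.lm_id, r.label, r.chi2, r.df, r.p_raw, r.p_adjusted)
         for r in results],
        columns=["dataset", "lm_id", "label", "chi2", "df", "p_raw", "p_adjusted"])


# ---------------------------------------------------------------------------
# multiple-comparison correction


def by_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values (arbitrary dependence).

    ``adj_(i) = min_{j >= i} min(1, p_(j) * m * c(m) / j)`` with
    ``c(m) = sum_{i=1..m} 1/i``; the output is returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]
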