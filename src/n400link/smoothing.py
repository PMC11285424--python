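"""Penalized B-spline smoother with per-group offsets.

A scikit-learn estimator for curves of the form

    y = f(x) + offset(group) + noise

where ``f`` is a cubic B-spline whose wiggliness is penalized by a
second-order coefficient-difference penalty and chosen by generalized
cross-validation.  Group offsets (one unpenalized column per non-reference
group level) absorb vertical shifts — adding a constant to every response of
one group changes only that group's offset, never the shape of ``f``.

``predict`` returns the population-level curve: the spline plus the mean of
the fitted offsets, i.e. the expected response for a new, unobserved group
(the "dummy language model" device used by the exponent estimator).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DegenerateInputError, InvalidInputError

__all__ = ["PenalizedBSplineGAM"]


def _as_group_matrix(groups, n: int) -> Optional[np.ndarray]:
    """Normalize ``groups`` to an (n, n_factors) object array of labels."""
    if groups is None:
        return None
    g = np.asarray(groups, dtype=object)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[0] != n:
        raise InvalidInputError("groups has wrong length")
    return g


class PenalizedBSplineGAM(RegressorMixin, BaseEstimator):
    """Penalized cubic B-spline regression with unpenalized group offsets.

    Parameters
    ----------
    n_splines : int, default 10
        Number of B-spline basis functions (basis dimension).
    degree : int, default 3
        Spline degree.
    penalty_order : int, default 2
        Order of the coefficient-difference penalty; its null space
        (polynomials up to ``penalty_order - 1`` in the coefficients)
        is never shrunk.
    lambdas : array-like, optional
        Candidate smoothing parameters searched by GCV
        (default ``logspace(-6, 8, 43)``).

    Attributes
    ----------
    coef_ : spline coefficients.
    offsets_ : fitted offset per group level (reference levels at 0).
    lambda_ : selected smoothing parameter.
    edf_ : effective degrees of freedom of the full fit.
    gcv_ : GCV score at ``lambda_``.
    adj_r2_ : adjusted R² of the fit (using ``edf_`` as model df).
    """

    def __init__(self, n_splines: int = 10, degree: int = 3,
                 penalty_order: int = 2, lambdas=None):
        self.n_splines = n_splines
        self.degree = degree
        self.penalty_order = penalty_order
        self.lambdas = lambdas

    # -- basis -------------------------------------------------------------
    def _knots(self, lo: float, hi: float) -> np.ndarray:
        k, m = self.degree, self.n_splines
        interior = np.linspace(lo, hi, m - k + 1)
        return np.concatenate([np.full(k, lo), interior, np.full(k, hi)])

    def _basis(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.domain_
        xc = np.clip(x, lo, hi)
        return BSpline.design_matrix(xc, self.knots_, self.degree).toarray()

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y, groups=None):
        X = check_array(X, ensure_2d=False, dtype=float)
        x = X.ravel() if X.ndim > 1 else X
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] != y.shape[0]:
            raise InvalidInputError("X and y have different lengths")
        n = x.shape[0]
        if self.n_splines < self.penalty_order + 1:
            raise InvalidInputError("n_splines too small for the penalty order")
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise DegenerateInputError("x has zero range")
        self.domain_ = (lo, hi)
        self.knots_ = self._knots(lo, hi)
        B = self._basis(x)
        m = B.shape[1]

        gm = _as_group_matrix(groups, n)
        offset_cols: List[np.ndarray] = []
        offset_names: List[tuple] = []
        self.group_levels_: List[List[str]] = []
        if gm is not None:
            for j in range(gm.shape[1]):
                codes, levels = pd.factorize(gm[:, j], sort=True)
                self.group_levels_.append([str(l) for l in levels])
                for lev in range(1, len(levels)):  # first level = reference
                    offset_cols.append((codes == lev).astype(float))
                    offset_names.append((j, lev))
        C = np.column_stack([B] + offset_cols) if offset_cols else B
        p = C.shape[1]

        D = np.diff(np.eye(m), n=self.penalty_order, axis=0)
        P = np.zeros((p, p))
        P[:m, :m] = D.T @ D

        CtC = C.T @ C
        Cty = C.T @ y
        yty = float(y @ y)
        ridge = 1e-9 * max(np.trace(CtC) / p, 1.0) * np.eye(p)

        lambdas = (np.logspace(-6, 8, 43) if self.lambdas is None
                   else np.asarray(self.lambdas, dtype=float))
        best = None
        for lam in lambdas:
            A = CtC + lam * P + ridge
            try:
                theta = linalg.solve(A, Cty, assume_a="pos")
                H = linalg.solve(A, CtC, assume_a="pos")
            except linalg.LinAlgError:
                continue
            edf = float(np.trace(H))
            rss = max(yty - 2 * float(Cty @ theta)
                      + float(theta @ (CtC @ theta)), 0.0)
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, theta, edf, rss)
        if best is None:
            raise DegenerateInputError("smoother failed for every lambda")

        self.gcv_, self.lambda_, theta, self.edf_, rss = best
        self.coef_ = theta[:m]
        offsets = theta[m:]
        self.offset_names_ = offset_names
        self.offsets_ = offsets
        # mean offset over *all* levels (references contribute 0)
        if gm is not None:
            means = []
            start = 0
            for j, levels in enumerate(self.group_levels_):
                cnt = len(levels) - 1
                means.append(np.sum(offsets[start:start + cnt]) / len(levels))
                start += cnt
            self.offset_mean_ = float(np.sum(means))
        else:
            self.offset_mean_ = 0.0

        tss = float(np.sum((y - y.mean()) ** 2))
        if tss > 0:
            self.adj_r2_ = 1.0 - (rss / max(n - self.edf_, 1e-8)) / (tss / (n - 1))
        else:
            self.adj_r2_ = float("nan")
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Population-level curve: spline + mean group offset."""
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_2d=False, dtype=float)
        x = X.ravel() if X.ndim > 1 else X
        return self._basis(x) @ self.coef_ + self.offset_mean_
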