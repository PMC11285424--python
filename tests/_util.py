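"""Shared test helpers and independent oracles.

The oracles deliberately avoid the package's own computational paths:
the mixed-model oracle optimizes the closed-form marginal Gaussian
likelihood on the full n x n covariance, and the FDR oracle is the step-up
formula written out directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from n400link.data import ModelFrame, RandomStructure


def make_ri_frame(y, X, codes, names=None, dataset_name="test") -> ModelFrame:
    """ModelFrame with a single subject random intercept, from raw arrays."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes = np.asarray(codes)
    names = names or ([f"x{i}" for i in range(X.shape[1])])
    names = ["Intercept"] + list(names)[1:] if names[0] != "Intercept" else names
    levels = [str(l) for l in sorted(set(codes.tolist()))]
    rs = RandomStructure(factor="subject", codes=codes, levels=levels)
    return ModelFrame(y=y, X=pd.DataFrame(X, columns=names),
                      random=[rs], data=pd.DataFrame({"subject": codes}),
                      dataset_name=dataset_name)


def brute_force_ri_loglik(y, X, codes) -> float:
    """ML log-likelihood of the random-intercept model by direct optimization.

    Builds the full marginal covariance sigma_b^2 Z Z' + sigma_e^2 I and
    maximizes the exact Gaussian log-likelihood over both log-variances from
    several starting points (Nelder-Mead); beta is profiled by GLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes = np.asarray(codes)
    n = len(y)
    G = codes.max() + 1
    Z = np.zeros((n, G))
    Z[np.arange(n), codes] = 1.0
    ZZt = Z @ Z.T

    def nll(theta):
        s2b, s2e = np.exp(theta)
        V = s2b * ZZt + s2e * np.eye(n)
        try:
            cf = linalg.cho_factor(V)
        except linalg.LinAlgError:
            return 1e300
        Vi_X = linalg.cho_solve(cf, X)
        Vi_y = linalg.cho_solve(cf, y)
        beta = linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = linalg.cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return 0.5 * (n * np.log(2 * np.pi) + logdet + float(r @ Vi_r))

    best = None
    for x0 in ([0.0, 0.0], [-2.0, 0.0], [1.0, -1.0], [-4.0, -4.0]):
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


def by_stepup(p) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values, direct step-up formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(1.0, p[idx] * m * c_m / rank_from_top)
        running_min = min(running_min, val)
        adjusted[idx] = running_min
    return adjusted
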