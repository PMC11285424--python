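import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from n400link import SimConfig, generate, preset_recipe
from n400link.data import build_design
from n400link.errors import (
    InvalidInputError,
    NotNestedError,
    RankDeficiencyError,
)
from n400link.mixedlm import (
    PARTITION_BATTERY,
    LmmFit,
    by_fdr,
    fit_lmm,
    likelihood_ratio,
    variance_partition,
)

from _util import brute_force_ri_loglik, by_stepup, make_ri_frame


def _ri_problem(rng, n_groups=6, per_group=12, beta=(0.5, -0.8)):
    n = n_groups * per_group
    codes = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.asarray(beta) + rng.normal(0, 0.9, n_groups)[codes] \
        + rng.normal(0, 1.2, n)
    return y, X, codes


def test_ml_deviance_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(5):
        y, X, codes = _ri_problem(rng)
        fit = fit_lmm(make_ri_frame(y, X, codes))
        oracle = brute_force_ri_loglik(y, X, codes)
        assert fit.deviance == pytest.approx(-2 * oracle, abs=1e-4)


def test_profiled_path_agrees_with_statsmodels():
    rng = np.random.default_rng(12)
    y, X, codes = _ri_problem(rng)
    frame = make_ri_frame(y, X, codes)
    fast = fit_lmm(frame)
    sm = fit_lmm(frame, method="statsmodels")
    assert fast.method == "profiled-ri" and sm.method == "statsmodels-mixedlm"
    assert fast.logLik == pytest.approx(sm.logLik, abs=1e-4)
    assert fast.n_params == sm.n_params
    for name in fast.fixed_estimates:
        assert fast.fixed_estimates[name] == pytest.approx(
            sm.fixed_estimates[name], abs=1e-4)


def test_crossed_vc_path_agrees_with_statsmodels(small_bundle):
    recipe = preset_recipe("baseline_covariates")
    metric = small_bundle.metric_values(small_bundle.lm_ids[0])["S"]
    frame = build_design(small_bundle.dataset, metric, recipe=recipe)
    fast = fit_lmm(frame, method="vc")
    sm = fit_lmm(frame, method="statsmodels")
    assert fast.n_params == sm.n_params
    # both maximize the same likelihood; ours may never trail
    assert fast.logLik >= sm.logLik - 1e-3
    if sm.converged:
        assert fast.logLik == pytest.approx(sm.logLik, abs=5e-3)


def test_small_crossed_problem_agrees_with_statsmodels():
    rng = np.random.default_rng(14)
    cfg = SimConfig(n_subjects=10, n_items=12, n_mock_lms=1)
    bundle = generate(cfg, seed=14)
    frame = build_design(bundle.dataset,
                         bundle.metric_values("lm00")["S"],
                         recipe=preset_recipe("baseline_covariates"))
    fast = fit_lmm(frame, method="vc")
    sm = fit_lmm(frame, method="statsmodels")
    assert sm.converged
    assert fast.logLik >= sm.logLik - 1e-4     # ours may never trail
    assert fast.logLik == pytest.approx(sm.logLik, abs=5e-3)


def test_aic_identity():
    fit = LmmFit(logLik=-123.456, n_params=7, fixed_estimates={},
                 variance_estimates={}, converged=True, singular=False,
                 n_obs=100, random_signature="(1|s)", method="test")
    assert fit.aic == 2 * 7 - 2 * (-123.456)


def test_duplicated_predictor_is_rank_deficient():
    rng = np.random.default_rng(13)
    y, X, codes = _ri_problem(rng)
    X_dup = np.column_stack([X, X[:, 1]])
    with pytest.raises(RankDeficiencyError):
        fit_lmm(make_ri_frame(y, X_dup, codes,
                              names=["Intercept", "x", "x_copy"]))


# -- likelihood-ratio tests --------------------------------------------------

def _fit_stub(loglik, terms, n=100, sig="(1|subject)"):
    return LmmFit(logLik=loglik, n_params=len(terms) + 2,
                  fixed_estimates={t: 0.0 for t in terms},
                  variance_estimates={}, converged=True, singular=False,
                  n_obs=n, random_signature=sig, method="test")


def test_identical_models_give_null_statistic():
    base = _fit_stub(-100.0, ["Intercept"])
    res = likelihood_ratio(base, base, df=1)
    assert res.chi2 == 0.0 and res.p_raw == 1.0


def test_lrt_reference_value():
    """logLik pair (-100, -94.065) gives chi2 = 11.87, p about 5.7e-4."""
    base = _fit_stub(-100.0, ["Intercept"])
    augmented = _fit_stub(-94.065, ["Intercept", "S"])
    res = likelihood_ratio(base, augmented, df=1)
    assert res.chi2 == pytest.approx(11.87, abs=1e-9)
    assert res.p_raw == pytest.approx(5.7e-4, rel=2e-2)


def test_non_nested_models_are_rejected():
    base = _fit_stub(-100.0, ["Intercept", "S"])
    other = _fit_stub(-99.0, ["Intercept", "P"])
    with pytest.raises(NotNestedError):
        likelihood_ratio(base, other, df=1)
    different_re = _fit_stub(-99.0, ["Intercept", "S", "P"], sig="(1|item)")
    with pytest.raises(NotNestedError):
        likelihood_ratio(base, different_re, df=1)


def test_worse_augmented_loglik_warns_and_clips():
    base = _fit_stub(-100.0, ["Intercept"])
    augmented = _fit_stub(-100.5, ["Intercept", "S"])
    with pytest.warns(UserWarning, match="clipped"):
        res = likelihood_ratio(base, augmented, df=1)
    assert res.chi2 == 0.0


def test_affine_dv_transform_leaves_lrt_and_delta_aic_invariant(small_bundle):
    """y -> a + b*y shifts every logLik by n log b; chi2 and delta-AIC survive."""
    mv = small_bundle.metric_values(small_bundle.lm_ids[0])
    frame = build_design(small_bundle.dataset, mv["S"], zscore_dv=False,
                         extra_metrics={"S^0.6": mv["S^0.6"]})
    scaled = frame.subset(["metric", "S^0.6"])
    scaled.y = 3.7 * frame.y - 11.0

    f_base = fit_lmm(frame.subset(["metric"]))
    f_full = fit_lmm(frame.subset(["metric", "S^0.6"]))
    g_base = fit_lmm(scaled.subset(["metric"]))
    g_full = fit_lmm(scaled.subset(["metric", "S^0.6"]))

    n = frame.n_obs
    shift = -n * np.log(3.7)
    assert g_base.logLik - f_base.logLik == pytest.approx(shift, abs=1e-5)
    chi_f = likelihood_ratio(f_base, f_full, df=1).chi2
    chi_g = likelihood_ratio(g_base, g_full, df=1).chi2
    assert chi_f == pytest.approx(chi_g, abs=1e-5)
    assert (f_full.aic - f_base.aic) == pytest.approx(
        g_full.aic - g_base.aic, abs=1e-5)


# -- variance partition -------------------------------------------------------

def test_partition_battery_structure(small_bundle):
    mv = small_bundle.metric_values(small_bundle.lm_ids[0])
    results = variance_partition(small_bundle.dataset, mv, lm_id="lm00")
    assert [r.label for r in results] == [lbl for lbl, _, _ in PARTITION_BATTERY]
    assert [r.df for r in results] == [1, 1, 1, 1, 1, 1, 1, 2]
    for r in results:
        assert r.p_adjusted >= r.p_raw - 1e-15
        assert r.chi2 >= 0.0


def test_partition_rejects_collinear_metrics(small_bundle):
    items = list(small_bundle.stimuli["item_id"])
    base = {i: float(v) for i, v in zip(items, np.linspace(1, 2, len(items)))}
    collinear = {"P": base,
                 "S": {i: 2 * v for i, v in base.items()},
                 "S^0.6": {i: 3 * v - 1 for i, v in base.items()}}
    with pytest.raises(RankDeficiencyError):
        variance_partition(small_bundle.dataset, collinear)


# -- Benjamini-Yekutieli ------------------------------------------------------

def test_by_fdr_hand_case():
    np.testing.assert_allclose(by_fdr([0.01, 0.04]), [0.03, 0.06], atol=1e-12)


def test_by_fdr_single_p_scaled_by_c1():
    # m = 1: c(1) = 1, adjustment is the identity
    np.testing.assert_allclose(by_fdr([0.2]), [0.2], atol=1e-15)


def test_by_fdr_ties_share_one_adjusted_value():
    p = [0.02, 0.02, 0.02]
    adj = by_fdr(p)
    c3 = 1 + 0.5 + 1 / 3
    assert np.all(adj == adj[0])
    assert adj[0] == pytest.approx(min(1.0, 0.02 * 3 * c3 / 3), abs=1e-12)


def test_by_fdr_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        by_fdr([0.5, 1.5])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_by_fdr_matches_direct_stepup_and_is_monotone(p):
    adj = by_fdr(p)
    np.testing.assert_allclose(adj, by_stepup(p), atol=1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)   # monotone in raw p
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(by_fdr(list(np.asarray(p)[perm])),
                               adj[perm], atol=1e-12)
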