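"""Double-hurdle estimators, effects, sandwich and ancillary panel models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from orgfield import hurdle, synthetic
from orgfield.config import TrueParams
from orgfield.hurdle import HurdleSpec

from conftest import design


# ---------------------------------------------------------------------------
# Hurdle 1: probit cross-checks
# ---------------------------------------------------------------------------

def test_tau_zero_probit_matches_statsmodels(tau0_frame):
    _, df = tau0_frame
    fit = hurdle.fit_first_hurdle(df, HurdleSpec(tau2=0.0))
    sm_fit = sm.Probit(df.spray_product.astype(float), design(df)).fit(
        disp=0, method="newton", tol=1e-12)
    assert np.abs(fit.params - sm_fit.params).max() < 1e-8
    # model-based SEs should agree with the probit information matrix
    assert np.abs(np.sqrt(np.diag(fit.vcov_model)) - sm_fit.bse).max() < 1e-5


def test_free_tau_on_homogeneous_data_collapses_to_probit(tau0_frame):
    _, df = tau0_frame
    fit = hurdle.fit_first_hurdle(df, HurdleSpec())
    assert fit.tau2 < 0.05
    sm_fit = sm.Probit(df.spray_product.astype(float), design(df)).fit(
        disp=0, method="newton", tol=1e-12)
    assert np.abs(fit.params - sm_fit.params).max() < 1e-2


def test_random_intercept_probit_recovers_truth(re_frame):
    params, df = re_frame
    fit = hurdle.fit_first_hurdle(df, HurdleSpec())
    for j, g in enumerate(params.gamma):
        est, se = fit.params[j], fit.se[j]
        assert abs(est - g) < 4 * se
    assert fit.tau2 == pytest.approx(params.tau2_h1, abs=0.15)


def test_constant_outcome_raises_separation_error(tau0_frame):
    _, df = tau0_frame
    bad = df.copy()
    bad["spray_product"] = True
    with pytest.raises(hurdle.SeparationError):
        hurdle.fit_first_hurdle(bad, HurdleSpec())


def test_singular_design_names_collinear_column(tau0_frame):
    _, df = tau0_frame
    bad = df.copy()
    bad["dup"] = np.log(bad.area_adj_ha)
    spec = HurdleSpec(covariates=("organic", "log_area", "log_farm", "storie", "dup"))
    with pytest.raises(np.linalg.LinAlgError, match="dup"):
        hurdle.fit_first_hurdle(bad, spec)


def test_quadrature_loglik_stable_in_node_count(re_frame):
    _, df = re_frame
    sub = df.iloc[:800]
    fit = hurdle.fit_first_hurdle(sub, HurdleSpec(n_nodes=20))
    from orgfield.hurdle import ProbitRE, _prepare
    d, X, _, codes, _ = _prepare(sub, HurdleSpec())
    y = d.spray_product.to_numpy(dtype=float)
    theta = np.r_[fit.params, np.sqrt(fit.tau2)]
    ll20 = ProbitRE(y, X, codes, n_nodes=20).loglik(theta, None)
    ll30 = ProbitRE(y, X, codes, n_nodes=30).loglik(theta, None)
    assert abs(ll20 - ll30) < 1e-6


# ---------------------------------------------------------------------------
# Hurdle 2: linear mixed model cross-checks
# ---------------------------------------------------------------------------

def test_tau_zero_lmm_equals_closed_form_ols(tau0_frame):
    _, df = tau0_frame
    pos = df[df.rate_product > 0]
    fit = hurdle.fit_second_hurdle(pos, HurdleSpec(tau2=0.0))
    X = design(pos)
    beta = np.linalg.lstsq(X, np.log(pos.rate_product), rcond=None)[0]
    assert np.abs(fit.params - beta).max() < 1e-8


def test_lmm_matches_statsmodels_mixedlm():
    params = TrueParams()
    df = synthetic.simulate_hurdle_frame(params, n_farms=300,
                                         fields_per_farm_mean=8.0, seed=4)
    pos = df[df.rate_product > 0]
    fit = hurdle.fit_second_hurdle(pos, HurdleSpec())
    X = design(pos)
    md = sm.MixedLM(np.log(pos.rate_product.to_numpy()), X,
                    groups=pos.group.to_numpy())
    sm_fit = md.fit(reml=False)
    assert np.abs(fit.params - np.asarray(sm_fit.fe_params)).max() < 1e-4
    assert fit.tau2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-3)
    assert fit.sigma2 == pytest.approx(sm_fit.scale, abs=1e-3)


def test_sigma2_recovered_within_tolerance():
    params = TrueParams(sigma2=0.25, tau2_h1=0.0, tau2_h2=0.1)
    df = synthetic.simulate_hurdle_frame(params, n_farms=1500, fields_per_farm_mean=8,
                                         seed=8)
    pos = df[df.rate_product > 0]
    fit = hurdle.fit_second_hurdle(pos, HurdleSpec())
    assert fit.sigma2 == pytest.approx(0.25, abs=0.02)


def test_second_hurdle_rejects_nonpositive_outcomes(tau0_frame):
    _, df = tau0_frame
    with pytest.raises(ValueError, match="positive"):
        hurdle.fit_second_hurdle(df, HurdleSpec())


def test_second_hurdle_rejects_single_observation(tau0_frame):
    _, df = tau0_frame
    one = df[df.rate_product > 0].iloc[:1]
    with pytest.raises(ValueError):
        hurdle.fit_second_hurdle(one, HurdleSpec())


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------

def test_ame_zero_when_organic_coefficient_zero(tau0_frame):
    _, df = tau0_frame
    fit = hurdle.fit_first_hurdle(df, HurdleSpec(tau2=0.0))
    fit.params[fit.names.index("organic")] = 0.0
    ame = hurdle.ame_organic(fit, df, HurdleSpec(tau2=0.0))
    assert ame.estimate == 0.0


def test_saturated_ame_equals_proportion_difference(tau0_frame):
    _, df = tau0_frame
    spec = HurdleSpec(covariates=("organic",), tau2=0.0)
    fit = hurdle.fit_first_hurdle(df, spec)
    ame = hurdle.ame_organic(fit, df, spec)
    p1 = df[df.organic].spray_product.mean()
    p0 = df[~df.organic].spray_product.mean()
    assert ame.estimate == pytest.approx(p1 - p0, abs=1e-6)


def test_population_averaged_ame_attenuates(re_frame):
    _, df = re_frame
    fit = hurdle.fit_first_hurdle(df, HurdleSpec())
    a0 = hurdle.ame_organic(fit, df, HurdleSpec())
    a1 = hurdle.ame_organic(fit, df, HurdleSpec(), population_averaged=True)
    assert abs(a1.estimate) < abs(a0.estimate)


@pytest.mark.parametrize("beta, se, est, sei", [
    (0.0, 0.1, 0.0, 10.0),
    (np.log(2.0), 0.0, 100.0, 0.0),
    (-1.0, 0.2, -63.21205588285577, 7.357588823428847),
])
def test_semi_elasticity_closed_form(beta, se, est, sei):
    e = hurdle.semi_elasticity(beta, se)
    assert e.estimate == pytest.approx(est, abs=1e-9)
    assert e.se == pytest.approx(sei, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.floats(-3, 3), st.floats(0, 2))
def test_semi_elasticity_se_matches_numeric_derivative(beta, se):
    e = hurdle.semi_elasticity(beta, se)
    h = 1e-7
    deriv = (100 * (np.exp(beta + h) - 1) - 100 * (np.exp(beta - h) - 1)) / (2 * h)
    assert e.se == pytest.approx(abs(deriv) * se, rel=1e-6, abs=1e-8)


def test_ihs_closed_form_values():
    assert hurdle.ihs(0.0) == 0.0
    assert hurdle.ihs(1.0, premultiplier=1.0) == pytest.approx(0.8813735870195430)
    x = 1e3
    assert hurdle.ihs(x, 100.0) - np.log(200.0 * x) == pytest.approx(0.0, abs=1e-8)


# ---------------------------------------------------------------------------
# Sandwich
# ---------------------------------------------------------------------------

def test_single_cluster_rejected():
    with pytest.raises(ValueError):
        hurdle.cluster_sandwich(np.ones((1, 2)), np.eye(2))


def test_iid_data_cluster_and_model_ses_agree():
    rng = np.random.default_rng(5)
    n = 10000
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([1.0, 0.5]) + rng.standard_normal(n)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ beta
    sigma2 = r @ r / n
    bread = np.linalg.inv(X.T @ X)
    clusters = rng.integers(0, 500, n)
    order = np.argsort(clusters)
    starts = np.flatnonzero(np.r_[True, np.diff(clusters[order]) != 0])
    Sg = np.add.reduceat((X * r[:, None])[order], starts, axis=0)
    vc = hurdle.cluster_sandwich(Sg, bread)
    se_cluster = np.sqrt(np.diag(vc))
    se_model = np.sqrt(np.diag(bread) * sigma2)
    assert np.all(np.abs(se_cluster / se_model - 1) < 0.10)


# ---------------------------------------------------------------------------
# Yield gap
# ---------------------------------------------------------------------------

def test_conventional_rows_unchanged_by_yield_gap(re_frame):
    _, df = re_frame
    adj = hurdle.apply_yield_gap(df, {"all_crops": 0.8})
    conv = ~df.organic
    assert np.array_equal(adj.loc[conv, "rate_product"], df.loc[conv, "rate_product"])
    org = df.organic & (df.rate_product > 0)
    assert np.allclose(adj.loc[org, "rate_product"], 0.8 * df.loc[org, "rate_product"])


def test_yield_gap_requires_default_multiplier(re_frame):
    _, df = re_frame
    with pytest.raises(Exception):
        hurdle.apply_yield_gap(df, {"vegetables": 0.9})


def test_crop_group_multiplier_applied_with_fallback():
    df = pd.DataFrame({
        "organic": [True, True, False],
        "crop_group": ["vegetables", None, "vegetables"],
        "rate_product": [10.0, 10.0, 10.0],
    })
    adj = hurdle.apply_yield_gap(df, {"vegetables": 0.9, "all_crops": 0.5})
    assert list(adj.rate_product) == [9.0, 5.0, 10.0]


# ---------------------------------------------------------------------------
# Crop-specific path
# ---------------------------------------------------------------------------

def _crop_frame(seed=0):
    params = TrueParams()
    df = synthetic.simulate_hurdle_frame(params, n_farms=400, seed=seed)
    rng = np.random.default_rng(seed)
    df = df.copy()
    df["crop"] = rng.choice(["carrot", "grape"], len(df))
    df["year"] = rng.choice([2013, 2014, 2015], len(df))
    return df


def test_crop_specific_equals_pooled_path_on_subset():
    df = _crop_frame()
    fit_a = hurdle.fit_crop_specific(df, "carrot", HurdleSpec(outcome="product"))
    sub = df[df.crop == "carrot"]
    spec = HurdleSpec(outcome="product", grouping="year", vcov="hc")
    fit_b = hurdle.fit_double_hurdle(sub, spec)
    assert np.allclose(fit_a.h1.params, fit_b.h1.params)
    assert np.allclose(fit_a.h2.params, fit_b.h2.params)


def test_crop_with_single_year_falls_back_without_intercept():
    df = _crop_frame()
    df["year"] = 2013
    with pytest.warns(UserWarning, match="<2 years"):
        fit = hurdle.fit_crop_specific(df, "grape", HurdleSpec(outcome="product"))
    assert fit.h1.tau2 == 0.0


def test_crop_missing_one_class_rejected():
    df = _crop_frame()
    df.loc[df.crop == "carrot", "organic"] = False
    with pytest.raises(ValueError, match="carrot"):
        hurdle.fit_crop_specific(df, "carrot", HurdleSpec(outcome="product"))


# ---------------------------------------------------------------------------
# Ancillary panel estimators
# ---------------------------------------------------------------------------

def _panel_frame(seed=0, group_effect=3.0, n=4000):
    """Crop-level intercepts correlated with organic share: pooled OLS is
    biased by construction, the within estimator is not."""
    rng = np.random.default_rng(seed)
    crop = rng.choice(["a", "b"], n)
    p_org = np.where(crop == "a", 0.1, 0.8)
    organic = rng.random(n) < p_org
    ystar = 2.0 + group_effect * (crop == "b") + 1.0 * organic + rng.normal(0, 0.2, n)
    return pd.DataFrame({
        "crop": crop, "organic": organic, "family": "F",
        "rate_product": np.sinh(ystar) / 100.0,
        "area_adj_ha": np.exp(rng.normal(2.7, 0.6, n)),
        "farm_size_ha": np.exp(rng.normal(5.5, 0.8, n)),
        "storie": rng.uniform(1, 6, n),
    })


def test_within_estimator_removes_group_confounding():
    df = _panel_frame()
    spec = HurdleSpec(outcome="product")
    within, _ = hurdle.fit_panel_ancillary(df, "within", spec, group_col="crop")
    pooled, _ = hurdle.fit_panel_ancillary(df, "pooled-ols", spec, group_col="crop")
    b_within = within.coef("organic")[0]
    b_pooled = pooled.coef("organic")[0]
    assert abs(b_within - 1.0) < 0.1
    assert abs(b_pooled - 1.0) > 0.5


def test_random_effects_collapse_to_pooled_without_heterogeneity():
    df = _panel_frame(group_effect=0.0)
    spec = HurdleSpec(outcome="product")
    re_fit, comp = hurdle.fit_panel_ancillary(df, "random-effects", spec, group_col="crop")
    pooled, _ = hurdle.fit_panel_ancillary(df, "pooled-ols", spec, group_col="crop")
    assert np.abs(re_fit.params - pooled.params).max() < 1e-4
    assert {"aic", "bic", "loglik"} <= set(comp)


def test_group_mean_differencing_zeroes_group_means():
    df = _panel_frame(n=1000)
    codes, _ = pd.factorize(df.crop)
    y = hurdle.ihs(df.rate_product.to_numpy())
    ybar = np.bincount(codes, weights=y) / np.bincount(codes)
    yd = y - ybar[codes]
    for g in np.unique(codes):
        assert np.mean(yd[codes == g]) == pytest.approx(0.0, abs=1e-10)


def test_within_estimator_requires_nonsingleton_groups():
    df = _panel_frame(n=50).assign(crop=[f"c{i}" for i in range(50)])
    with pytest.raises(ValueError):
        hurdle.fit_panel_ancillary(df, "within", HurdleSpec(outcome="product"),
                                   group_col="crop")
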