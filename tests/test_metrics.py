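"""Use-rate construction, soil extraction/imputation and the fish PTI."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from orgfield import metrics
from orgfield.synthetic import StorieSurface

KEY = ["permit", "site", "year"]


def _fields(rows, **extra):
    df = pd.DataFrame(rows, columns=KEY + ["field_id", "area_ha"])
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# Multi-crop area division
# ---------------------------------------------------------------------------

def test_area_split_equally_among_simultaneous_crops():
    f = _fields([("P1", "S1", 2013, "F1", 30.0),
                 ("P1", "S2", 2013, "F1", 30.0),
                 ("P1", "S3", 2013, "F1", 30.0),
                 ("P2", "S4", 2013, "F2", 12.0)])
    out = metrics.divide_multicrop_area(f)
    assert np.allclose(out[out.field_id == "F1"].area_adj_ha, 10.0)
    assert np.allclose(out[out.field_id == "F2"].area_adj_ha, 12.0)


def test_multicrop_division_conserves_total_area(messy_bundle):
    _, bundle = messy_bundle
    out = metrics.divide_multicrop_area(bundle["fields"])
    per_field = out.groupby(["field_id", "year"]).agg(
        adj=("area_adj_ha", "sum"), raw=("area_ha", "first"))
    assert np.allclose(per_field.adj, per_field.raw)


def test_zero_area_field_rejected():
    f = _fields([("P1", "S1", 2013, "F1", 0.0)])
    with pytest.raises(ValueError):
        metrics.divide_multicrop_area(f)


# ---------------------------------------------------------------------------
# Use rates
# ---------------------------------------------------------------------------

def _catalog():
    return pd.DataFrame({
        "product_id": ["INS", "DUAL", "FISH", "SAFE"],
        "type": ["insecticide", "dual-action", "fungicide", "other"],
        "ai_fraction": [0.4, 0.5, 0.2, 0.0],
        "fish": [False, False, True, False],
        "bee": [False, False, False, False],
        "aquatic": [False] * 4,
        "drift": [False] * 4,
        "signal_word": [1, 3, 2, 0],
    })


def test_rate_arithmetic_product_and_ai():
    f = _fields([("P1", "S1", 2013, "F1", 2.0)])
    apps = pd.DataFrame([{"app_id": "A0", "permit": "P1", "site": "S1", "year": 2013,
                          "product_id": "INS", "product_kg": 5.0, "ai_kg": 2.0}])
    out = metrics.compute_use_rates(apps, f, _catalog())
    assert out.rate_product.iloc[0] == pytest.approx(2.5)
    assert out.rate_ai.iloc[0] == pytest.approx(1.0)
    assert bool(out.spray_product.iloc[0])


def test_category_membership_rules():
    f = _fields([("P1", "S1", 2013, "F1", 1.0)])
    apps = pd.DataFrame([
        {"app_id": "A0", "permit": "P1", "site": "S1", "year": 2013,
         "product_id": "INS", "product_kg": 1.0, "ai_kg": 0.4},
        {"app_id": "A1", "permit": "P1", "site": "S1", "year": 2013,
         "product_id": "DUAL", "product_kg": 1.0, "ai_kg": 0.5},
        {"app_id": "A2", "permit": "P1", "site": "S1", "year": 2013,
         "product_id": "FISH", "product_kg": 1.0, "ai_kg": 0.2},
    ])
    out = metrics.compute_use_rates(apps, f, _catalog()).iloc[0]
    assert out.rate_insecticide == pytest.approx(1.0)  # dual-action excluded
    assert out.rate_fish == pytest.approx(1.0)  # only the flagged product
    assert out.rate_high_tox == pytest.approx(2.0)  # signal words 1 and 2
    assert out.rate_low_tox == pytest.approx(1.0)  # signal words 3/4/none


def test_category_rates_bounded_by_product_rate(messy_bundle):
    _, bundle = messy_bundle
    out = metrics.compute_use_rates(bundle["applications"], bundle["fields"],
                                    bundle["products"])
    tol = 1e-9
    for cat in ("insecticide", "drift", "fish", "bee", "high_tox", "low_tox"):
        assert (out[f"rate_{cat}"] <= out.rate_product + tol).all()
    assert (out.rate_ai <= out.rate_product + tol).all()
    for o in ("ai", "product", "fish"):
        assert ((out[f"rate_{o}"] > 0) == out[f"spray_{o}"]).all()


def test_application_on_unknown_field_raises():
    f = _fields([("P1", "S1", 2013, "F1", 1.0)])
    apps = pd.DataFrame([{"app_id": "A0", "permit": "P9", "site": "S9", "year": 2013,
                          "product_id": "INS", "product_kg": 1.0, "ai_kg": 0.4}])
    with pytest.raises(KeyError):
        metrics.compute_use_rates(apps, f, _catalog())


# ---------------------------------------------------------------------------
# Soil extraction
# ---------------------------------------------------------------------------

def _surface(values, cell=10.0):
    return StorieSurface(x0=0.0, y0=0.0, cell=cell, values=np.asarray(values, dtype=float))


def test_storie_single_class_region():
    surf = _surface(np.full((4, 4), 2.0))
    assert metrics.area_weighted_storie(box(5, 5, 25, 25), surf) == pytest.approx(2.0)


def test_storie_even_split_between_two_classes():
    vals = np.ones((4, 4))
    vals[:, 2:] = 3.0
    surf = _surface(vals)
    # field spans [10,30]x[0,40]: half over class 1, half over class 3
    assert metrics.area_weighted_storie(box(10, 0, 30, 40), surf) == pytest.approx(2.0)


def test_storie_all_missing_returns_nan():
    surf = _surface(np.full((4, 4), np.nan))
    assert np.isnan(metrics.area_weighted_storie(box(5, 5, 25, 25), surf))


def test_storie_bounded_by_overlapped_values():
    rng = np.random.default_rng(0)
    surf = _surface(rng.integers(1, 7, (8, 8)).astype(float))
    val = metrics.area_weighted_storie(box(7, 13, 44, 61), surf)
    assert 1.0 <= val <= 6.0


def test_storie_translation_invariance_for_aligned_fields():
    vals = np.tile(np.array([[1.0, 3.0]]), (4, 2))
    a = metrics.area_weighted_storie(box(0, 0, 20, 20), _surface(vals))
    b = metrics.area_weighted_storie(
        box(100, 100, 120, 120),
        StorieSurface(x0=100.0, y0=100.0, cell=10.0, values=vals))
    assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# IDW imputation
# ---------------------------------------------------------------------------

def test_idw_exact_at_coincident_point():
    known = np.array([[0.0, 0.0], [10.0, 0.0]])
    vals = np.array([1.0, 5.0])
    out, _ = metrics.idw_impute(np.array([[0.0, 0.0]]), known, vals)
    assert out[0] == pytest.approx(1.0)


def test_idw_constant_field_everywhere():
    rng = np.random.default_rng(1)
    known = rng.uniform(0, 100, (50, 2))
    out, rmse = metrics.idw_impute(rng.uniform(0, 100, (20, 2)), known,
                                   np.full(50, 3.0))
    assert np.allclose(out, 3.0)
    assert rmse == pytest.approx(0.0, abs=1e-12)


def test_idw_loocv_rmse_small_on_smooth_surface():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 1000, (400, 2))
    # smooth storie-like gradient in [1, 5]
    vals = 3.0 + 2.0 * np.sin(pts[:, 0] / 400.0) * np.cos(pts[:, 1] / 400.0)
    _, rmse = metrics.idw_impute(pts[:5], pts, vals, power=2.0, n_loocv=200, seed=0)
    assert rmse < 0.5


def test_idw_requires_known_points():
    with pytest.raises(ValueError):
        metrics.idw_impute(np.array([[0.0, 0.0]]), np.empty((0, 2)), np.empty(0))


# ---------------------------------------------------------------------------
# Fish PTI
# ---------------------------------------------------------------------------

def _pti_setup(products, tox):
    f = _fields([("P1", "S1", 2013, "F1", 1.0)])
    prods = pd.DataFrame(products)
    toxt = pd.DataFrame(tox)
    return f, prods, toxt


def test_pti_zero_use_included_with_full_coverage():
    f, prods, toxt = _pti_setup(
        [{"product_id": "A", "ai_code": "C1", "ai_fraction": 1.0}],
        [{"ai_code": "C1", "fish_tox": 4.0}])
    out = metrics.pti_fish(pd.DataFrame(columns=["app_id"] + KEY
                                        + ["product_id", "product_kg", "ai_kg"]),
                           f, prods, toxt)
    assert out.pti_fish.iloc[0] == 0.0
    assert out.pti_coverage.iloc[0] == 1.0
    assert bool(out.pti_include.iloc[0])


def test_pti_quotient_arithmetic():
    f, prods, toxt = _pti_setup(
        [{"product_id": "A", "ai_code": "C1", "ai_fraction": 1.0}],
        [{"ai_code": "C1", "fish_tox": 4.0}])
    apps = pd.DataFrame([{"app_id": "A0", "permit": "P1", "site": "S1", "year": 2013,
                          "product_id": "A", "product_kg": 2.0, "ai_kg": 2.0}])
    out = metrics.pti_fish(apps, f, prods, toxt)
    assert out.pti_fish.iloc[0] == pytest.approx(0.5)  # 2 kg/ha over tox 4


def test_pti_coverage_threshold_excludes_field():
    prods = [{"product_id": f"P{i}", "ai_code": f"C{i}", "ai_fraction": 1.0}
             for i in range(5)]
    tox = [{"ai_code": f"C{i}", "fish_tox": 2.0 if i < 3 else np.nan}
           for i in range(5)]
    f, prods, toxt = _pti_setup(prods, tox)
    apps = pd.DataFrame([{"app_id": f"A{i}", "permit": "P1", "site": "S1",
                          "year": 2013, "product_id": f"P{i}",
                          "product_kg": 1.0, "ai_kg": 1.0} for i in range(5)])
    out = metrics.pti_fish(apps, f, prods, toxt, coverage_threshold=0.7)
    assert out.pti_coverage.iloc[0] == pytest.approx(0.6)
    assert not bool(out.pti_include.iloc[0])


def test_pti_linear_in_masses():
    f, prods, toxt = _pti_setup(
        [{"product_id": "A", "ai_code": "C1", "ai_fraction": 0.5}],
        [{"ai_code": "C1", "fish_tox": 3.0}])
    apps = pd.DataFrame([{"app_id": "A0", "permit": "P1", "site": "S1", "year": 2013,
                          "product_id": "A", "product_kg": 2.0, "ai_kg": 1.0}])
    base = metrics.pti_fish(apps, f, prods, toxt).pti_fish.iloc[0]
    doubled = apps.assign(product_kg=apps.product_kg * 2, ai_kg=apps.ai_kg * 2)
    assert metrics.pti_fish(doubled, f, prods, toxt).pti_fish.iloc[0] == pytest.approx(2 * base)


def test_pti_rejects_nonpositive_toxicity():
    f, prods, toxt = _pti_setup(
        [{"product_id": "A", "ai_code": "C1", "ai_fraction": 1.0}],
        [{"ai_code": "C1", "fish_tox": -1.0}])
    with pytest.raises(ValueError):
        metrics.pti_fish(pd.DataFrame(columns=["app_id"] + KEY
                                      + ["product_id", "product_kg", "ai_kg"]),
                         f, prods, toxt)
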