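"""Field-year analysis-table construction.

Turns raw fields, application records, the product catalog and the soil
raster into one row per permit-site-year with adjusted area, farm size,
area-weighted soil grade, organic label, and pesticide use rates (kg/ha) per
outcome class, plus the preliminary fish Pesticide Toxicity Index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from orgfield.config import OUTCOMES
from orgfield.synthetic import StorieSurface

KEY = ["permit", "site", "year"]

#: Product types counted as insecticide use.  Dual-action products
#: (insecticide + fungicide) are excluded; insecticides with adjuvant or
#: fertilizer additives are not.
INSECTICIDE_TYPES = {"insecticide", "insect-growth-regulator", "miticide", "repellent"}


def divide_multicrop_area(fields: pd.DataFrame) -> pd.DataFrame:
    """Split field area equally among crops grown simultaneously on it.

    Simultaneous crops share permit, year and geometry (``field_id``) under
    distinct site ids; each crop-row's adjusted area is the field area divided
    by the number of such rows, so total area is conserved exactly.
    """
    if (fields.area_ha <= 0).any():
        bad = fields.loc[fields.area_ha <= 0, KEY].head()
        raise ValueError(f"zero/negative field area for rows:\n{bad}")
    fields = fields.copy()
    if "field_id" in fields.columns:
        n = fields.groupby(["field_id", "year"])["site"].transform("size")
    else:
        n = fields.get("n_crops", pd.Series(1, index=fields.index))
    fields["n_crops"] = n
    fields["area_adj_ha"] = fields.area_ha / n
    return fields


def compute_use_rates(applications: pd.DataFrame, fields: pd.DataFrame,
                      products: pd.DataFrame) -> pd.DataFrame:
    """Per field-year use rates (kg/ha) for every outcome class.

    * ``ai``: active-ingredient mass / adjusted area;
    * ``product``: product mass / adjusted area;
    * hazard classes (insecticide, drift, fish, bee, high_tox, low_tox) sum
      product mass over products matching the class definition — product mass
      rather than AI mass, since adjuvant-only products can carry hazards.

    High toxicity is EPA signal word 1-2; low is 3, 4 or not required (0).
    Raises if an application references a field-year absent from ``fields``.
    """
    fields = fields if "area_adj_ha" in fields.columns else divide_multicrop_area(fields)
    fkeys = pd.MultiIndex.from_frame(fields[KEY])
    akeys = pd.MultiIndex.from_frame(applications[KEY]) if len(applications) else None
    if akeys is not None:
        missing = ~akeys.isin(fkeys)
        if missing.any():
            raise KeyError(
                f"applications reference unknown fields: "
                f"{applications.loc[missing, KEY].drop_duplicates().head().values.tolist()}")

    cat = products.set_index("product_id")
    apps = applications.copy()
    for col, mask in _class_masks(cat).items():
        apps[f"mass_{col}"] = np.where(apps.product_id.map(mask), apps.product_kg, 0.0)
    apps["mass_ai"] = apps.ai_kg
    apps["mass_product"] = apps.product_kg

    sums = apps.groupby(KEY)[[f"mass_{o}" for o in OUTCOMES]].sum().reset_index()
    out = fields.merge(sums, on=KEY, how="left")
    for o in OUTCOMES:
        col = f"mass_{o}"
        out[col] = out[col].fillna(0.0)
        out[f"rate_{o}"] = out[col] / out.area_adj_ha
        out[f"spray_{o}"] = out[f"rate_{o}"] > 0
        out = out.drop(columns=[col])
    return out


def _class_masks(cat: pd.DataFrame) -> dict[str, pd.Series]:
    insecticide = cat.type.isin(INSECTICIDE_TYPES)
    return {
        "insecticide": insecticide,
        "drift": cat.drift.astype(bool),
        "fish": cat.fish.astype(bool),
        "bee": cat.bee.astype(bool),
        "high_tox": cat.signal_word.isin([1, 2]),
        "low_tox": cat.signal_word.isin([3, 4, 0]),
    }


# ---------------------------------------------------------------------------
# Soil
# ---------------------------------------------------------------------------

def area_weighted_storie(geom, surface: StorieSurface) -> float:
    """Area-weighted mean soil grade of the raster cells under a polygon.

    Missing (NaN) cells contribute no weight; returns NaN when no overlapping
    cell has a value.  The result is bounded by the min/max of overlapped
    values and is exact for polygons aligned with cell edges.
    """
    surface.validate()
    vals = surface.values
    nrows, ncols = vals.shape
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(int(np.floor((minx - surface.x0) / surface.cell)), 0)
    j1 = min(int(np.ceil((maxx - surface.x0) / surface.cell)), ncols)
    i0 = max(int(np.floor((miny - surface.y0) / surface.cell)), 0)
    i1 = min(int(np.ceil((maxy - surface.y0) / surface.cell)), nrows)
    if j0 >= j1 or i0 >= i1:
        return float("nan")
    from shapely.geometry import box as _box

    total_w = 0.0
    acc = 0.0
    for i in range(i0, i1):
        y0 = surface.y0 + i * surface.cell
        for j in range(j0, j1):
            v = vals[i, j]
            if np.isnan(v):
                continue
            x0 = surface.x0 + j * surface.cell
            w = geom.intersection(_box(x0, y0, x0 + surface.cell, y0 + surface.cell)).area
            if w > 0:
                acc += w * v
                total_w += w
    return acc / total_w if total_w > 0 else float("nan")


def extract_storie(fields: pd.DataFrame, surface: StorieSurface) -> pd.Series:
    """Vectorized area-weighted extraction over a fields table (one value per
    distinct geometry, broadcast to rows)."""
    cache: dict = {}
    out = np.empty(len(fields))
    for k, (fid, geom) in enumerate(zip(fields.get("field_id", fields.index), fields.geometry)):
        if fid not in cache:
            cache[fid] = area_weighted_storie(geom, surface)
        out[k] = cache[fid]
    return pd.Series(out, index=fields.index)


def idw_impute(query_xy: np.ndarray, known_xy: np.ndarray, known_values: np.ndarray,
               power: float = 2.0, n_neighbors: int | None = None,
               n_loocv: int = 500, seed: int = 0):
    """Inverse-distance-weighted interpolation with leave-one-out validation.

    ``value = sum(w_i v_i) / sum(w_i)`` with ``w_i = d_i ** -power``; a query
    coinciding with a known point returns that point's value.  LOOCV is run on
    ``min(n_loocv, n_known)`` randomly selected known points and its RMSE
    reported.  Returns ``(imputed values, loocv_rmse)``.
    """
    known_xy = np.asarray(known_xy, dtype=float)
    known_values = np.asarray(known_values, dtype=float)
    query_xy = np.asarray(query_xy, dtype=float).reshape(-1, 2)
    if len(known_xy) == 0:
        raise ValueError("idw_impute requires at least one known point")

    def _predict(qxy: np.ndarray, kxy: np.ndarray, kv: np.ndarray) -> np.ndarray:
        if n_neighbors is not None and n_neighbors < len(kxy):
            tree = cKDTree(kxy)
            d, idx = tree.query(qxy, k=n_neighbors)
            v = kv[idx]
        else:
            d = np.linalg.norm(qxy[:, None, :] - kxy[None, :, :], axis=2)
            v = np.broadcast_to(kv, d.shape)
        exact = d < 1e-12
        with np.errstate(divide="ignore"):
            w = d ** (-power)
        w = np.where(exact, 0.0, w)
        out = np.where(
            exact.any(axis=1),
            v[np.arange(len(qxy)), np.where(exact.any(axis=1), exact.argmax(axis=1), 0)],
            (w * v).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300),
        )
        return out

    imputed = _predict(query_xy, known_xy, known_values)

    rng = np.random.default_rng(seed)
    n_cv = min(n_loocv, len(known_xy))
    if len(known_xy) > 1 and n_cv > 0:
        pick = rng.choice(len(known_xy), size=n_cv, replace=False)
        errs = np.empty(n_cv)
        for t, i in enumerate(pick):
            mask = np.ones(len(known_xy), dtype=bool)
            mask[i] = False
            pred = _predict(known_xy[i:i + 1], known_xy[mask], known_values[mask])
            errs[t] = pred[0] - known_values[i]
        rmse = float(np.sqrt(np.mean(errs ** 2)))
    else:
        rmse = float("nan")
    return imputed, rmse


# ---------------------------------------------------------------------------
# Fish Pesticide Toxicity Index
# ---------------------------------------------------------------------------

def pti_fish(applications: pd.DataFrame, fields: pd.DataFrame,
             products: pd.DataFrame, tox_table: pd.DataFrame,
             coverage_threshold: float = 0.7) -> pd.DataFrame:
    """Toxicity-weighted use sum for the fish endpoint, per field-year.

    PTI = sum over matched active ingredients of (AI use rate / toxicity
    value); exposure is proxied by the use rate (kg/ha) since ambient
    concentrations are unobserved.  Coverage is the fraction of distinct AIs
    on the field with a toxicity record; fields at or above
    ``coverage_threshold`` get ``pti_include=True``.  Zero-pesticide fields
    have PTI 0 with coverage 1.
    """
    tox = tox_table.set_index("ai_code").fish_tox
    if (tox.dropna() <= 0).any():
        raise ValueError("fish toxicity values must be positive")
    fields = fields if "area_adj_ha" in fields.columns else divide_multicrop_area(fields)
    cat = products.set_index("product_id")
    apps = applications.merge(fields[KEY + ["area_adj_ha"]], on=KEY)
    apps["ai_code"] = apps.product_id.map(cat.ai_code)
    apps = apps[apps.ai_code.fillna("") != ""]
    apps["tox"] = apps.ai_code.map(tox)
    apps["ai_rate"] = apps.ai_kg / apps.area_adj_ha
    apps["quotient"] = np.where(apps.tox.notna(), apps.ai_rate / apps.tox, 0.0)

    def _agg(g: pd.DataFrame) -> pd.Series:
        chems = g.drop_duplicates("ai_code")
        matched = chems.tox.notna()
        coverage = matched.mean() if len(chems) else 1.0
        return pd.Series({
            "pti_fish": g.quotient.sum(),
            "pti_coverage": coverage,
        })

    if len(apps):
        agg = apps.groupby(KEY).apply(_agg, include_groups=False).reset_index()
    else:
        agg = pd.DataFrame(columns=KEY + ["pti_fish", "pti_coverage"])
    out = fields[KEY].drop_duplicates().merge(agg, on=KEY, how="left")
    out["pti_fish"] = out.pti_fish.astype(float).fillna(0.0)
    out["pti_coverage"] = out.pti_coverage.astype(float).fillna(1.0)
    out["pti_include"] = out.pti_coverage >= coverage_threshold
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def build_analysis_table(fields: pd.DataFrame, applications: pd.DataFrame,
                         products: pd.DataFrame, labels: pd.DataFrame,
                         surface: StorieSurface | None = None,
                         tox_table: pd.DataFrame | None = None,
                         idw_power: float = 2.0,
                         pti_threshold: float = 0.7,
                         seed: int = 0) -> pd.DataFrame:
    """Assemble the per-field-year analysis table.

    Joins organic labels, computes adjusted areas and farm sizes, extracts
    area-weighted soil grades (imputing missing ones by IDW from field
    centroids, flagged ``storie_imputed``), builds use rates for every outcome
    and appends the fish PTI columns when a toxicity table is given.
    """
    df = divide_multicrop_area(fields)
    df["farm_size_ha"] = df.groupby(["permit", "year"])["area_adj_ha"].transform("sum")
    lab = labels.drop(columns=[c for c in labels.columns if c not in KEY + ["organic", "registry_organic"]])
    df = df.drop(columns=[c for c in ("organic",) if c in df.columns])
    df = df.merge(lab, on=KEY, how="left")
    df["organic"] = df.organic.fillna(False).astype(bool)

    if surface is not None and "geometry" in df.columns:
        df["storie"] = extract_storie(df, surface)
        missing = df.storie.isna()
        df["storie_imputed"] = missing
        if missing.any() and (~missing).any():
            cx = df.geometry.apply(lambda g: g.centroid.x)
            cy = df.geometry.apply(lambda g: g.centroid.y)
            known = np.column_stack([cx[~missing], cy[~missing]])
            vals, _ = idw_impute(
                np.column_stack([cx[missing], cy[missing]]), known,
                df.storie[~missing].to_numpy(), power=idw_power, seed=seed)
            df.loc[missing, "storie"] = vals
    elif "storie" not in df.columns and "storie_centroid" in df.columns:
        df["storie"] = df.storie_centroid
        df["storie_imputed"] = False

    df = compute_use_rates(applications, df, products)
    if tox_table is not None:
        pti = pti_fish(applications, df, products, tox_table, pti_threshold)
        df = df.merge(pti, on=KEY, how="left")
    df["missing_family"] = df.family.isna()
    return df
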