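"""Synthetic county-scale data generator.

Generates, from a fixed seed, every input the identification and analysis
stages need: a planar landscape of survey sections, tax parcels and crop
fields (axis-aligned rectangles on a meter grid), a soil-grade raster, a
pesticide product catalog with hazard flags and organic evidence, field-level
application records drawn from a two-part probit/lognormal process with
farm-by-crop-family random intercepts, and a certification registry whose
identifier strings are deliberately corrupted the way real free-text entry
corrupts them.

Ground truth (which fields are organic, each field's spray propensity and
latent amount, each product's class) is returned alongside so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import norm
from shapely.geometry import box

from orgfield.config import ConfigurationError, SimConfig, TrueParams

# ---------------------------------------------------------------------------
# Crop taxonomy
# ---------------------------------------------------------------------------

#: name -> (taxonomic family or None, perennial, yield-gap commodity group or None)
CROP_TABLE: dict[str, tuple[str | None, bool, str | None]] = {
    "carrot": ("Apiaceae", False, "vegetables"),
    "potato": ("Solanaceae", False, "roots_tubers"),
    "onion": ("Amaryllidaceae", False, "vegetables"),
    "lettuce_leaf": ("Asteraceae", False, "vegetables"),
    "tomato": ("Solanaceae", False, "vegetables"),
    "grape": ("Vitaceae", True, "fruits"),
    "orange": ("Rutaceae", True, "fruits"),
    "almond": ("Rosaceae", True, None),
    "alfalfa": ("Fabaceae", False, "legumes_pulses"),
    "wheat": ("Poaceae", False, "cereals"),
    # Uncultivated agriculture: no taxonomic family, never sprayed heavily in
    # the real data; exercises the missing-family drop rules downstream.
    "uncultivated_ag": (None, False, None),
}

_CROP_NAMES = list(CROP_TABLE)
_CROP_WEIGHTS = np.array([0.12, 0.08, 0.05, 0.08, 0.08, 0.14, 0.10, 0.14, 0.10, 0.06, 0.05])
_CROP_WEIGHTS = _CROP_WEIGHTS / _CROP_WEIGHTS.sum()

PRODUCT_TYPES = (
    "insecticide",
    "insect-growth-regulator",
    "miticide",
    "repellent",
    "fungicide",
    "dual-action",
    "herbicide",
    "adjuvant-only",
    "other",
)

#: Columns of the model design matrix, in order.
COVARIATES = ("const", "organic", "log_area", "log_farm", "storie")


@dataclass
class StorieSurface:
    """Regular soil-grade raster: ``values[i, j]`` covers
    ``x in [x0 + j*cell, x0 + (j+1)*cell)``, ``y in [y0 + i*cell, ...)``.
    Missing cells are NaN."""

    x0: float
    y0: float
    cell: float
    values: np.ndarray  # 2-D float array, NaN = missing

    def validate(self) -> None:
        if self.cell <= 0:
            raise ConfigurationError("cell size must be positive")


@dataclass
class TruthBundle:
    """Planted truth for scoring recovery."""

    field_truth: pd.DataFrame  # per field-year-crop row: keys + organic_true,
    # spray_prob, latent_log_rate
    product_truth: pd.DataFrame  # product_id, organic_true
    organic_farms: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "organic_farms": self.organic_farms,
            "field_truth": self.field_truth.to_dict(orient="list"),
            "product_truth": self.product_truth.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        payload = json.loads(Path(path).read_text())
        return cls(
            field_truth=pd.DataFrame(payload["field_truth"]),
            product_truth=pd.DataFrame(payload["product_truth"]),
            organic_farms=payload["organic_farms"],
        )


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _split_rect(rect: tuple[float, float, float, float], k: int, rng: np.random.Generator,
                min_side: float = 120.0) -> list[tuple[float, float, float, float]]:
    """Split an axis-aligned rectangle into ``k`` rectangles by guillotine cuts."""
    rects = [rect]
    while len(rects) < k:
        # split the largest rectangle along its longer side
        idx = max(range(len(rects)), key=lambda i: (rects[i][2] - rects[i][0]) * (rects[i][3] - rects[i][1]))
        x0, y0, x1, y1 = rects.pop(idx)
        w, h = x1 - x0, y1 - y0
        frac = 0.5 if max(w, h) < 2 * min_side else float(rng.uniform(0.35, 0.65))
        if w >= h:
            xm = x0 + frac * w
            rects.extend([(x0, y0, xm, y1), (xm, y0, x1, y1)])
        else:
            ym = y0 + frac * h
            rects.extend([(x0, y0, x1, ym), (x0, ym, x1, y1)])
    return rects


def _apn(i: int) -> str:
    """Deterministic unique canonical APN (3-3-2 digit segments) for parcel i."""
    return f"{101 + i // 100:03d}-{i % 100:03d}-{i % 90:02d}"


def simulate_landscape(config: SimConfig):
    """Build the nested section → parcel → field landscape plus the soil raster.

    Returns ``(parcels, sections, fields, surface)`` where the first three are
    DataFrames carrying shapely geometries and ``surface`` is a
    :class:`StorieSurface`.  Fields are rectangles nested in parcels, parcels
    are quadrants of square sections, and every field-year-crop row carries
    permit id, site id, year, crop and crop family.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_fields_per_farm = 1 + rng.poisson(config.fields_per_farm_mean - 1.0, config.n_farms)
    mu, sg = config.field_area_lognormal_params

    # Allocate parcels to farms until each farm's field quota is met; each
    # parcel is subdivided into a number of fields implied by a lognormal
    # target field area.
    parcel_edge = config.grid_cell_m / 2.0
    parcel_area_ha = parcel_edge * parcel_edge / 1e4
    parcel_farm: list[int] = []
    parcel_nfields: list[int] = []
    for f in range(config.n_farms):
        remaining = int(n_fields_per_farm[f])
        while remaining > 0:
            target = float(rng.lognormal(mu, sg))
            k = int(np.clip(round(parcel_area_ha / max(target, 1.0)), 1, 6))
            k = min(k, remaining)
            parcel_farm.append(f)
            parcel_nfields.append(k)
            remaining -= k
    n_parcels = len(parcel_farm)
    n_sections = -(-n_parcels // 4)
    side = int(np.ceil(np.sqrt(n_sections)))

    sec_rows = []
    for s in range(n_sections):
        r, c = divmod(s, side)
        x0, y0 = c * config.grid_cell_m, r * config.grid_cell_m
        trs = f"{25 + r}S{20 + c}E{(s % 36) + 1:02d}"
        sec_rows.append({
            "section_id": f"SEC{s:04d}", "trs": trs,
            "township": f"{25 + r}S", "range": f"{20 + c}E", "section": (s % 36) + 1,
            "geometry": box(x0, y0, x0 + config.grid_cell_m, y0 + config.grid_cell_m),
        })
    sections = pd.DataFrame(sec_rows)

    parcel_rows, field_rows = [], []
    fid = 0
    for p in range(n_parcels):
        s, q = divmod(p, 4)
        r, c = divmod(s, side)
        qx, qy = divmod(q, 2)
        x0 = c * config.grid_cell_m + qx * parcel_edge
        y0 = r * config.grid_cell_m + qy * parcel_edge
        rect = (x0, y0, x0 + parcel_edge, y0 + parcel_edge)
        parcel_rows.append({
            "parcel_id": f"PAR{p:05d}", "apn": _apn(p),
            "section_id": f"SEC{s:04d}", "farm": f"P{parcel_farm[p]:04d}",
            "geometry": box(*rect),
        })
        for fr in _split_rect(rect, parcel_nfields[p], rng):
            field_rows.append({
                "field_id": f"F{fid:05d}", "parcel_id": f"PAR{p:05d}",
                "section_id": f"SEC{s:04d}", "permit": f"P{parcel_farm[p]:04d}",
                "x0": fr[0], "y0": fr[1], "x1": fr[2], "y1": fr[3],
            })
            fid += 1
    parcels = pd.DataFrame(parcel_rows)
    phys = pd.DataFrame(field_rows)
    phys["area_ha"] = (phys.x1 - phys.x0) * (phys.y1 - phys.y0) / 1e4
    phys["geometry"] = [box(x0, y0, x1, y1) for x0, y0, x1, y1 in
                        zip(phys.x0, phys.y0, phys.x1, phys.y1)]

    surface = _simulate_surface(config, side, rng)
    phys["storie_centroid"] = _sample_surface(
        surface, (phys.x0 + phys.x1) / 2.0, (phys.y0 + phys.y1) / 2.0
    )

    # Expand physical fields to field-year-crop observations.  Perennial
    # fields keep one crop for the whole window; annual fields rotate.
    perennial = {c for c, (_, per, _) in CROP_TABLE.items() if per}
    years = [config.first_year + t for t in range(config.n_years)]
    rows = []
    fixed_crop = {}
    for _, f in phys.iterrows():
        crop0 = str(rng.choice(_CROP_NAMES, p=_CROP_WEIGHTS))
        if crop0 in perennial:
            fixed_crop[f.field_id] = crop0
    site_counter = {y: 0 for y in years}
    for _, f in phys.iterrows():
        for y in years:
            if f.field_id in fixed_crop:
                crops = [fixed_crop[f.field_id]]
            else:
                crops = [str(rng.choice(_CROP_NAMES, p=_CROP_WEIGHTS))]
                if rng.random() < config.multicrop_share:
                    other = str(rng.choice(_CROP_NAMES, p=_CROP_WEIGHTS))
                    if other != crops[0]:
                        crops.append(other)
            for crop in crops:
                site_counter[y] += 1
                fam, _, grp = CROP_TABLE[crop]
                rows.append({
                    "permit": f.permit, "site": f"S{site_counter[y]:06d}", "year": y,
                    "field_id": f.field_id, "parcel_id": f.parcel_id,
                    "section_id": f.section_id, "crop": crop, "family": fam,
                    "crop_group": grp, "area_ha": f.area_ha, "n_crops": len(crops),
                    "storie_centroid": f.storie_centroid,
                    "x0": f.x0, "y0": f.y0, "x1": f.x1, "y1": f.y1,
                })
    fields = pd.DataFrame(rows)
    fields["n_crops"] = fields.groupby(["field_id", "year"])["site"].transform("size")
    geom = phys.set_index("field_id").geometry
    fields["geometry"] = fields.field_id.map(geom)
    return parcels, sections, fields, surface


def _simulate_surface(config: SimConfig, side: int, rng: np.random.Generator) -> StorieSurface:
    extent = side * config.grid_cell_m
    n = max(int(np.ceil(extent / config.storie_cell_m)), 4)
    raw = rng.standard_normal((n, n))
    smooth = ndimage.gaussian_filter(raw, sigma=max(n / 20.0, 2.0), mode="nearest")
    z = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    lv = np.asarray(config.storie_levels, dtype=float)
    grades = np.clip(np.round(1.8 + 1.1 * z), lv.min(), lv.max())
    if config.missing_soil_share > 0:
        # one rectangular missing blob, as SSURGO-style gaps tend to be contiguous
        h = max(int(np.sqrt(config.missing_soil_share) * n), 1)
        i0 = int(rng.integers(0, max(n - h, 1)))
        j0 = int(rng.integers(0, max(n - h, 1)))
        grades[i0:i0 + h, j0:j0 + h] = np.nan
    return StorieSurface(x0=0.0, y0=0.0, cell=config.storie_cell_m, values=grades)


def _sample_surface(surface: StorieSurface, xs, ys) -> np.ndarray:
    j = np.clip(((np.asarray(xs) - surface.x0) / surface.cell).astype(int), 0,
                surface.values.shape[1] - 1)
    i = np.clip(((np.asarray(ys) - surface.y0) / surface.cell).astype(int), 0,
                surface.values.shape[0] - 1)
    vals = surface.values[i, j]
    # fall back to the overall mean where the blob is missing; the DGP needs a
    # covariate everywhere, while metrics handles missingness explicitly
    fill = np.nanmean(surface.values)
    return np.where(np.isnan(vals), fill, vals)


# ---------------------------------------------------------------------------
# Management (organic assignment)
# ---------------------------------------------------------------------------

def simulate_management(fields: pd.DataFrame, params: TrueParams, config: SimConfig,
                        rng: np.random.Generator | None = None):
    """Assign certified-organic status at the farm level.

    Adoption probability is ``Phi(Phi^-1(share) + c_size * z(log farm area)
    - c_soil * z(mean soil grade))`` so that larger farms and better soil can
    be made more likely to host organic fields (both knobs 0 ⇒ independent
    Bernoulli draws at exactly ``organic_farm_share``).

    Returns ``(fields with an 'organic' column, partial TruthBundle)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fields = fields.copy()
    farm = fields.groupby("permit").agg(
        size_ha=("area_ha", "sum"), soil=("storie_centroid", "mean"))
    share = config.organic_farm_share
    if share <= 0.0:
        organic_farms: list[str] = []
    elif share >= 1.0:
        organic_farms = list(farm.index)
    else:
        z_size = _zscore(np.log(farm.size_ha.to_numpy()))
        z_soil = _zscore(farm.soil.to_numpy())
        score = (norm.ppf(share)
                 + config.organic_size_corr * z_size
                 - config.organic_soil_corr * z_soil)
        draws = rng.random(len(farm))
        organic_farms = list(farm.index[draws < norm.cdf(score)])
    fields["organic"] = fields.permit.isin(organic_farms)
    truth = TruthBundle(
        field_truth=fields[["permit", "site", "year", "organic"]]
        .rename(columns={"organic": "organic_true"}).copy(),
        product_truth=pd.DataFrame(columns=["product_id", "organic_true"]),
        organic_farms=sorted(organic_farms),
    )
    return fields, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# Product catalog
# ---------------------------------------------------------------------------

def simulate_products(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the product catalog with hazard flags and organic evidence.

    Each product carries a type, an active-ingredient (chemical) code and mass
    fraction, binary hazard flags (fish/bee/aquatic/drift), an acute-toxicity
    signal word, the true organic class, and the evidence fields
    (label/OMRI/ingredients) the classification cascade consumes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = config.n_products
    organic_true = rng.random(n) < config.organic_product_share
    adjuvant = rng.random(n) < config.adjuvant_share
    type_probs = np.array([0.22, 0.04, 0.05, 0.03, 0.20, 0.0, 0.16, 0.0, 0.30])
    types = np.array([str(t) for t in rng.choice(
        np.array(PRODUCT_TYPES, dtype=object), size=n, p=type_probs / type_probs.sum())])
    dual = (~adjuvant) & (rng.random(n) < config.dual_action_share)
    types[dual] = "dual-action"
    types[adjuvant] = "adjuvant-only"
    ai_fraction = np.where(adjuvant, 0.0, rng.uniform(0.1, 1.0, n))
    ai_code = np.array([f"CHEM{c:03d}" for c in rng.integers(0, config.n_chemicals, n)])
    ai_code[adjuvant] = ""

    # signal words: conventional skew toxic (1-2), organic skew 3/4/none (0)
    sw_conv = rng.choice([1, 2, 3, 4, 0], size=n, p=[0.15, 0.25, 0.30, 0.20, 0.10])
    sw_org = rng.choice([1, 2, 3, 4, 0], size=n, p=[0.02, 0.08, 0.30, 0.35, 0.25])
    if config.hazard_differs_by_class:
        signal_word = np.where(organic_true, sw_org, sw_conv)
    else:
        signal_word = sw_conv

    flags = {}
    for flag, p_conv, p_org in (("fish", 0.35, 0.15), ("bee", 0.25, 0.10),
                                ("aquatic", 0.30, 0.12), ("drift", 0.40, 0.25)):
        if not config.hazard_differs_by_class:
            p_org = p_conv
        flags[flag] = np.where(organic_true, rng.random(n) < p_org, rng.random(n) < p_conv)

    # evidence routes for true-organic products: label wording, OMRI listing,
    # or fully known organic ingredients — mirroring how a reviewer would
    # classify them; a configurable share has no evidence at all.
    route = rng.choice(["label", "omri", "ingredients"], size=n, p=[0.77, 0.22, 0.01])
    unclassified = rng.random(n) < config.unclassified_product_share
    label_organic = organic_true & (route == "label") & ~unclassified
    omri_listed = organic_true & (route == "omri") & ~unclassified
    ingredients_known = organic_true & (route == "ingredients") & ~unclassified

    return pd.DataFrame({
        "product_id": [f"PROD{i:04d}" for i in range(n)],
        "name": [f"Product {i}" for i in range(n)],
        "type": types,
        "ai_fraction": ai_fraction,
        "ai_code": ai_code,
        "fish": flags["fish"], "bee": flags["bee"],
        "aquatic": flags["aquatic"], "drift": flags["drift"],
        "signal_word": signal_word,
        "organic_true": organic_true,
        "label_organic": label_organic,
        "omri_listed": omri_listed,
        "ingredients_known_organic": ingredients_known,
        "active": ~(organic_true & unclassified) | organic_true,  # inactive only matters for provenance
    })


def simulate_tox_table(products: pd.DataFrame, config: SimConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fish-toxicity lookup for a ``tox_coverage`` share of chemicals.

    Toxicity values are lognormal "concentration at effect" style numbers;
    smaller = more toxic.  Organic-leaning chemicals are given no worse
    coverage here; coverage bias can be studied by editing the table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    chems = sorted(c for c in products.ai_code.unique() if c)
    covered = rng.random(len(chems)) < config.tox_coverage
    tox = np.exp(rng.normal(1.0, 1.5, len(chems)))
    return pd.DataFrame({
        "ai_code": chems,
        "fish_tox": np.where(covered, tox, np.nan),
    })


# ---------------------------------------------------------------------------
# Applications (the two-part DGP)
# ---------------------------------------------------------------------------

def design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Model design matrix ``[1, organic, log area, log farm size, storie]``."""
    return np.column_stack([
        np.ones(len(df)),
        df["organic"].to_numpy(dtype=float),
        np.log(df["area_adj_ha"].to_numpy(dtype=float)),
        np.log(df["farm_size_ha"].to_numpy(dtype=float)),
        df["storie"].to_numpy(dtype=float),
    ])


def _attach_covariates(fields: pd.DataFrame) -> pd.DataFrame:
    fields = fields.copy()
    fields["area_adj_ha"] = fields.area_ha / fields.n_crops
    farm_size = fields.groupby(["permit", "year"])["area_adj_ha"].transform("sum")
    fields["farm_size_ha"] = farm_size
    fields["storie"] = fields["storie_centroid"]
    return fields


def simulate_applications(fields: pd.DataFrame, products: pd.DataFrame,
                          params: TrueParams, config: SimConfig,
                          rng: np.random.Generator | None = None):
    """Draw spray decisions and application records from the two-part process.

    Spray ~ Bernoulli(Phi(x'gamma + u_g)); total product mass per hectare,
    conditional on spraying, is LogNormal(x'beta + v_g, sigma2).  The mass is
    split over 1 + Poisson draws of application events; organic fields draw
    products exclusively from the organically classified catalog subset,
    conventional fields from the full catalog.

    Returns ``(applications, truth_frame)`` where ``truth_frame`` carries the
    per-row spray propensity and latent log rate.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    org_products = products.loc[products.organic_true, "product_id"].to_numpy()
    if len(org_products) == 0:
        raise ConfigurationError("product catalog has no organic-classified subset")
    all_products = products.product_id.to_numpy()
    ai_frac = products.set_index("product_id").ai_fraction

    df = _attach_covariates(fields)
    X = design_matrix(df)
    group = df.permit.astype(str) + "|" + df.family.fillna("<none>").astype(str)
    codes, _ = pd.factorize(group)
    n_groups = codes.max() + 1
    u = rng.normal(0.0, np.sqrt(params.tau2_h1), n_groups)
    if params.correlated_intercepts:
        v = u * (np.sqrt(params.tau2_h2) / max(np.sqrt(params.tau2_h1), 1e-12))
    else:
        v = rng.normal(0.0, np.sqrt(params.tau2_h2), n_groups)

    eta1 = X @ np.asarray(params.gamma)
    spray_prob = norm.cdf(eta1 + u[codes])
    spray = rng.random(len(df)) < spray_prob
    eta2 = X @ np.asarray(params.beta) + v[codes]
    log_rate = eta2 + rng.normal(0.0, np.sqrt(params.sigma2), len(df))

    truth = df[["permit", "site", "year"]].copy()
    truth["spray_prob"] = spray_prob
    truth["latent_log_rate"] = log_rate
    truth["spray"] = spray

    rows = []
    n_apps = 1 + rng.poisson(config.mean_apps_per_spray - 1.0, int(spray.sum()))
    app_id = 0
    for (idx, k) in zip(np.flatnonzero(spray), n_apps):
        total_kg = np.exp(log_rate[idx]) * df.area_adj_ha.iloc[idx]
        shares = rng.dirichlet(np.ones(k))
        pool = org_products if df.organic.iloc[idx] else all_products
        prods = rng.choice(pool, size=k)
        for s, pid in zip(shares, prods):
            mass = total_kg * s
            rows.append({
                "app_id": f"A{app_id:07d}",
                "permit": df.permit.iloc[idx], "site": df.site.iloc[idx],
                "year": df.year.iloc[idx], "product_id": pid,
                "product_kg": mass, "ai_kg": mass * float(ai_frac[pid]),
            })
            app_id += 1
    applications = pd.DataFrame(
        rows, columns=["app_id", "permit", "site", "year", "product_id",
                       "product_kg", "ai_kg"])
    return applications, truth


def calibrate_organic_gamma(fields: pd.DataFrame, gamma_base: np.ndarray,
                            target_ame: float) -> float:
    """Find the organic probit coefficient producing a given average marginal effect.

    ``gamma_base`` supplies coefficients for ``[const, log_area, log_farm,
    storie]``; the returned value is the organic coefficient such that
    ``mean(Phi(eta + g) - Phi(eta)) == target_ame`` over the supplied fields'
    covariates (random intercept at zero).
    """
    df = _attach_covariates(fields) if "area_adj_ha" not in fields.columns else fields
    Z = np.column_stack([
        np.ones(len(df)), np.log(df["area_adj_ha"]), np.log(df["farm_size_ha"]),
        df["storie"]])
    eta = Z @ np.asarray(gamma_base, dtype=float)

    def gap(g: float) -> float:
        return float(np.mean(norm.cdf(eta + g) - norm.cdf(eta))) - target_ame

    return brentq(gap, -8.0, 8.0)


# ---------------------------------------------------------------------------
# Registry corruption
# ---------------------------------------------------------------------------

_SEPARATORS = ["; ", ", ", " ", "\n", ";", ","]


def _corrupt_apn(apn: str, messiness: dict[str, float], rng: np.random.Generator) -> str:
    """Apply at most one corruption class to a canonical ``xxx-xxx-xx`` APN."""
    classes = ["strip_leading_zeros", "append_digit", "remove_dashes",
               "extra_segment", "truncate_digits"]
    probs = np.array([messiness.get(c, 0.0) for c in classes])
    if probs.sum() <= 0 or rng.random() >= min(probs.sum(), 1.0):
        return apn
    choice = rng.choice(classes, p=probs / probs.sum())
    segs = apn.split("-")
    if choice == "strip_leading_zeros":
        return "-".join(s.lstrip("0") or "0" for s in segs)
    if choice == "append_digit":
        i = int(rng.integers(0, 3))
        segs[i] = segs[i] + str(rng.integers(0, 10))
        return "-".join(segs)
    if choice == "remove_dashes":
        return apn.replace("-", "")
    if choice == "extra_segment":
        return apn + f"-{rng.integers(10, 100):02d}"
    # truncate_digits: unrepairable by design (digits only, < 8 characters)
    return apn.replace("-", "")[:7]


def corrupt_registry(fields: pd.DataFrame, parcels: pd.DataFrame,
                     sections: pd.DataFrame, config: SimConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit one registry row per organic farm-year, with messy identifiers.

    APN rows pack all of the farm's parcel numbers into a single free-text
    cell with mixed separators; TRS rows (share ``registry_trs_share``) list
    the farm's sections one row each, with prefix/padding noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 5)
    messiness = config.registry_messiness
    org = fields.loc[fields.organic, ["permit", "year", "parcel_id", "section_id"]]
    parcel_apn = parcels.set_index("parcel_id").apn
    sec = sections.set_index("section_id")
    rows = []
    for (permit, year), grp in org.groupby(["permit", "year"]):
        company = f"{permit} Growers LLC"
        if rng.random() < config.registry_trs_share:
            for sid in sorted(grp.section_id.unique()):
                t, r, s = sec.loc[sid, "township"], sec.loc[sid, "range"], int(sec.loc[sid, "section"])
                s_txt = f"{s:02d}"
                if rng.random() < messiness.get("trs_unpad", 0.0):
                    s_txt = str(s)
                if rng.random() < messiness.get("trs_prefix", 0.0):
                    t = "T" + t
                    r = "R" + r
                    s_txt = str(rng.choice(["S", "Sec. ", "Section "])) + s_txt
                rows.append({"company": company, "year": year, "raw_apn": "",
                             "raw_township": t, "raw_range": r, "raw_section": s_txt})
        else:
            apns = [_corrupt_apn(parcel_apn[p], messiness, rng)
                    for p in sorted(grp.parcel_id.unique())]
            text = apns[0]
            for a in apns[1:]:
                text += str(rng.choice(_SEPARATORS)) + a
            rows.append({"company": company, "year": year, "raw_apn": text,
                         "raw_township": "", "raw_range": "", "raw_section": ""})
    return pd.DataFrame(
        rows, columns=["company", "year", "raw_apn", "raw_township",
                       "raw_range", "raw_section"])


# ---------------------------------------------------------------------------
# Fast covariate-level DGP (no geometry) for estimator studies
# ---------------------------------------------------------------------------

def simulate_hurdle_frame(params: TrueParams, n_farms: int = 250,
                          fields_per_farm_mean: float = 8.0,
                          organic_share: float = 0.3,
                          seed: int = 0) -> pd.DataFrame:
    """Draw an analysis-table-shaped frame straight from the two-part process.

    Skips geometry, registry and catalog machinery: covariates are drawn from
    the same distributions the landscape generator induces, and the outcome is
    the total product use rate.  Intended for estimator recovery and coverage
    studies where only the statistical model matters.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n_fields = 1 + rng.poisson(fields_per_farm_mean - 1.0, n_farms)
    permit = np.repeat([f"P{f:04d}" for f in range(n_farms)], n_fields)
    n = len(permit)
    organic_farm = rng.random(n_farms) < organic_share
    organic = np.repeat(organic_farm, n_fields)
    log_area = rng.normal(2.7, 0.6, n)
    log_farm = np.repeat(rng.normal(5.5, 0.8, n_farms), n_fields)
    storie = np.clip(np.round(rng.normal(1.8, 0.9, n)), 1, 6)
    family = rng.choice(
        ["Apiaceae", "Solanaceae", "Vitaceae", "Rutaceae", "Rosaceae", "Poaceae"], size=n)
    df = pd.DataFrame({
        "permit": permit, "site": [f"S{i:06d}" for i in range(n)],
        "year": 2013, "family": family, "organic": organic,
        "area_adj_ha": np.exp(log_area), "farm_size_ha": np.exp(log_farm),
        "storie": storie,
    })
    group = df.permit + "|" + df.family
    codes, _ = pd.factorize(group)
    u = rng.normal(0.0, np.sqrt(params.tau2_h1), codes.max() + 1)
    v = rng.normal(0.0, np.sqrt(params.tau2_h2), codes.max() + 1)
    X = design_matrix(df)
    spray = rng.random(n) < norm.cdf(X @ np.asarray(params.gamma) + u[codes])
    log_rate = (X @ np.asarray(params.beta) + v[codes]
                + rng.normal(0.0, np.sqrt(params.sigma2), n))
    df["group"] = group
    df["spray_product"] = spray
    df["rate_product"] = np.where(spray, np.exp(log_rate), 0.0)
    df["true_spray_prob"] = norm.cdf(X @ np.asarray(params.gamma) + u[codes])
    return df


# ---------------------------------------------------------------------------
# Bundle generation + disk round trip
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, params: TrueParams):
    """Run every generator stage; returns a dict of tables plus the truth bundle."""
    parcels, sections, fields, surface = simulate_landscape(config)
    fields, truth = simulate_management(fields, params, config)
    products = simulate_products(config)
    tox = simulate_tox_table(products, config)
    applications, app_truth = simulate_applications(fields, products, params, config)
    truth.product_truth = products[["product_id", "organic_true"]].copy()
    truth.field_truth = truth.field_truth.merge(
        app_truth, on=["permit", "site", "year"], how="left")
    registry = corrupt_registry(fields, parcels, sections, config)
    return {
        "parcels": parcels, "sections": sections, "fields": fields,
        "surface": surface, "products": products, "tox": tox,
        "applications": applications, "registry": registry, "truth": truth,
    }


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write all synthetic layers in plain-text formats (CSV/GeoJSON/ASC/JSON)."""
    from orgfield import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fields = bundle["fields"].drop(columns=["geometry"])
    fields.to_csv(outdir / "fields.csv", index=False)
    bundle["applications"].to_csv(outdir / "applications.csv", index=False)
    bundle["products"].to_csv(outdir / "products.csv", index=False)
    bundle["tox"].to_csv(outdir / "tox_fish.csv", index=False)
    bundle["registry"].to_csv(outdir / "registry.csv", index=False)
    io.write_geojson(bundle["parcels"], outdir / "parcels.geojson")
    io.write_geojson(bundle["sections"], outdir / "sections.geojson")
    io.write_asc(bundle["surface"], outdir / "soil.asc")
    bundle["truth"].to_json(outdir / "truth.json")
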