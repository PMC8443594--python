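"""Iterative refinement of registry-derived organic candidates.

Spatial joins alone over-identify organic fields (section-level locations,
parcel/field geometry mismatch), so the candidate set is refined against the
pesticide application records: products used on candidate fields are
classified organic/conventional in batches of the most-used unclassified
products, candidates that applied any conventionally classified product are
eliminated, and the loop repeats until every product appearing on surviving
candidates is classified.  Zero-pesticide candidates keep their registry
flag; zero-pesticide fields without the flag stay conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

KEY = ["permit", "site", "year"]


@dataclass
class ProductEvidence:
    """Facts a reviewer would extract about one product."""

    label_organic: bool = False
    omri_match: bool = False
    ingredients_known_organic: bool = False
    active: bool = True


@dataclass
class Classification:
    organic_class: str  # "organic" | "conventional"
    provenance: str  # "label" | "omri" | "ingredients" | "default-conventional"


def classify_product(product_id: str, evidence: ProductEvidence) -> Classification:
    """Classify one product from its evidence; first matching rule wins.

    Cascade: organic wording on the label -> OMRI listing -> fully known
    organic ingredients -> otherwise conventional (conservative default, which
    also covers inactive/unresolvable products).
    """
    if evidence.label_organic:
        return Classification("organic", "label")
    if evidence.omri_match:
        return Classification("organic", "omri")
    if evidence.ingredients_known_organic:
        return Classification("organic", "ingredients")
    return Classification("conventional", "default-conventional")


def catalog_classifier(products: pd.DataFrame):
    """Build a product_id -> Classification lookup from catalog evidence columns."""
    lookup = {}
    for _, row in products.iterrows():
        ev = ProductEvidence(
            label_organic=bool(row.get("label_organic", False)),
            omri_match=bool(row.get("omri_listed", False)),
            ingredients_known_organic=bool(row.get("ingredients_known_organic", False)),
            active=bool(row.get("active", True)),
        )
        lookup[row.product_id] = classify_product(row.product_id, ev)
    return lookup


def rank_products(candidates: pd.DataFrame, applications: pd.DataFrame,
                  top_n: int) -> list[str]:
    """Products used on candidate fields, by descending application count.

    Ties break by ascending product id; the first ``top_n`` are returned.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    cand = candidates[KEY].drop_duplicates()
    apps = applications.merge(cand, on=KEY)
    counts = apps.groupby("product_id").size().reset_index(name="n")
    counts = counts.sort_values(["n", "product_id"], ascending=[False, True])
    return counts.product_id.head(top_n).tolist()


@dataclass
class RefinementState:
    iteration: int
    n_candidates: int
    n_classified: int
    newly_classified: list[str] = field(default_factory=list)
    eliminated: int = 0


def refine_organic(candidates: pd.DataFrame, applications: pd.DataFrame,
                   products: pd.DataFrame, fields: pd.DataFrame,
                   top_n: int = 50):
    """Run the iterative elimination; returns ``(labels, history)``.

    ``labels`` is one row per field-year in ``fields`` with boolean
    ``registry_organic`` (registry candidate) and final ``organic`` columns.
    Fields outside the candidate set are never promoted to organic.

    Raises if an application references a product id missing from the catalog.
    """
    unknown = set(applications.product_id) - set(products.product_id)
    if unknown:
        raise KeyError(f"applications reference unknown product ids: {sorted(unknown)[:10]}")

    classifier = catalog_classifier(products)
    cand = candidates[KEY].drop_duplicates().copy()
    cand_idx = pd.MultiIndex.from_frame(cand)
    apps = applications.merge(cand, on=KEY)

    classified: dict[str, Classification] = {}
    history: list[RefinementState] = []
    remaining = cand
    it = 0
    while True:
        it += 1
        apps_rem = apps.merge(remaining, on=KEY)
        used = set(apps_rem.product_id)
        unclassified = used - set(classified)
        if not unclassified or len(remaining) == 0:
            history.append(RefinementState(it, len(remaining), len(classified)))
            break
        sub = apps_rem[apps_rem.product_id.isin(unclassified)]
        batch = rank_products(remaining, sub, top_n)
        for pid in batch:
            classified[pid] = classifier[pid]
        conv = {p for p, c in classified.items() if c.organic_class == "conventional"}
        bad = apps_rem.loc[apps_rem.product_id.isin(conv), KEY].drop_duplicates()
        bad_idx = pd.MultiIndex.from_frame(bad)
        keep = ~pd.MultiIndex.from_frame(remaining).isin(bad_idx)
        n_elim = int((~keep).sum())
        remaining = remaining[keep]
        history.append(RefinementState(it, len(remaining), len(classified), batch, n_elim))

    labels = fields[KEY + ["crop"]].drop_duplicates(KEY).copy() if "crop" in fields.columns \
        else fields[KEY].drop_duplicates().copy()
    labels["registry_organic"] = pd.MultiIndex.from_frame(labels[KEY]).isin(cand_idx)
    sprayed = set(map(tuple, applications[KEY].drop_duplicates().itertuples(index=False)))
    surviving = set(map(tuple, remaining.itertuples(index=False)))
    keys = list(map(tuple, labels[KEY].itertuples(index=False)))
    organic = []
    for key, is_cand in zip(keys, labels.registry_organic):
        if not is_cand:
            organic.append(False)
        elif key in sprayed:
            # candidate that sprayed: organic only if it survived elimination
            organic.append(key in surviving)
        else:
            # zero-pesticide candidate keeps its registry flag
            organic.append(True)
    labels["organic"] = organic
    return labels, history


def brute_force_labels(candidates: pd.DataFrame, applications: pd.DataFrame,
                       products: pd.DataFrame, fields: pd.DataFrame) -> pd.DataFrame:
    """Oracle labeling straight from the fully classified catalog.

    A candidate is organic iff it used no conventionally classified product
    (zero-pesticide candidates count as organic); non-candidates are
    conventional.  Used to verify order-robustness of the iterative path.
    """
    classifier = catalog_classifier(products)
    conv = {p for p, c in classifier.items() if c.organic_class == "conventional"}
    cand_idx = pd.MultiIndex.from_frame(candidates[KEY].drop_duplicates())
    labels = fields[KEY].drop_duplicates().copy()
    labels["registry_organic"] = pd.MultiIndex.from_frame(labels[KEY]).isin(cand_idx)
    bad = applications.loc[applications.product_id.isin(conv), KEY].drop_duplicates()
    bad_idx = pd.MultiIndex.from_frame(bad)
    labels["organic"] = labels.registry_organic & ~pd.MultiIndex.from_frame(labels[KEY]).isin(bad_idx)
    return labels
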