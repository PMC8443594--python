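"""Configuration dataclasses for the simulator, the models and the pipeline.

All configuration is plain-dataclass + YAML so that a pipeline run is fully
described by one file and one integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _default_messiness() -> dict[str, float]:
    # Probability, per registry token, of each corruption class.  All classes
    # except ``truncate_digits`` are repairable by the harmonization rules.
    return {
        "strip_leading_zeros": 0.25,
        "append_digit": 0.15,
        "remove_dashes": 0.25,
        "extra_segment": 0.10,
        "truncate_digits": 0.0,
        "trs_prefix": 0.5,
        "trs_unpad": 0.5,
    }


@dataclass
class SimConfig:
    """Knobs of the synthetic landscape, catalog and registry generator.

    The defaults emulate the structure of a single intensively farmed county:
    farms hold a handful of fields nested in tax parcels, parcels nest in
    square-mile survey sections, roughly one farm in twelve is certified
    organic, and a soil-productivity grade surface (1 best … 6 unproductive)
    is rasterized at 60 m.
    """

    n_farms: int = 150
    fields_per_farm_mean: float = 5.0
    #: (mu, sigma) of log field area in log-hectares; controls how finely
    #: parcels are subdivided into fields.
    field_area_lognormal_params: tuple[float, float] = (2.7, 0.6)
    organic_farm_share: float = 0.08
    #: Section edge length in meters (parcels are section quadrants).
    grid_cell_m: float = 1600.0
    #: Soil raster resolution in meters.
    storie_cell_m: float = 60.0
    storie_levels: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_products: int = 300
    organic_product_share: float = 0.25
    #: Share of products left "unclassified" in the catalog (no label, OMRI or
    #: ingredient evidence); the refinement stage treats those conservatively.
    unclassified_product_share: float = 0.0
    #: Share of adjuvant-only products (zero active-ingredient fraction).
    adjuvant_share: float = 0.08
    dual_action_share: float = 0.05
    n_chemicals: int = 80
    #: Share of chemicals with a fish-toxicity record in the synthetic table.
    tox_coverage: float = 0.7
    #: If True (default), organic products carry hazard flags and toxic signal
    #: words less often than conventional ones, as on real labels.  Set False
    #: for a catalog whose hazard profile is identical across classes — the
    #: sharp-null configuration for placebo checks on class-specific outcomes.
    hazard_differs_by_class: bool = True
    registry_messiness: dict[str, float] = field(default_factory=_default_messiness)
    #: Share of organic farm-years reporting section (TRS) locations instead
    #: of parcel numbers.  Section-level location is inherently ambiguous, so
    #: exact recovery of planted truth requires 0.
    registry_trs_share: float = 0.0
    n_years: int = 3
    first_year: int = 2013
    multicrop_share: float = 0.05
    #: Correlation knobs tying farm-level organic adoption to farm size and
    #: to soil quality (0 = independent).
    organic_size_corr: float = 0.6
    organic_soil_corr: float = 0.3
    #: Share of soil-raster cells masked as missing (one rectangular blob).
    missing_soil_share: float = 0.02
    mean_apps_per_spray: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "organic_farm_share": self.organic_farm_share,
            "organic_product_share": self.organic_product_share,
            "unclassified_product_share": self.unclassified_product_share,
            "adjuvant_share": self.adjuvant_share,
            "dual_action_share": self.dual_action_share,
            "tox_coverage": self.tox_coverage,
            "registry_trs_share": self.registry_trs_share,
            "multicrop_share": self.multicrop_share,
            "missing_soil_share": self.missing_soil_share,
            **{f"registry_messiness[{k}]": v for k, v in self.registry_messiness.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for name, c in {
            "n_farms": self.n_farms,
            "n_products": self.n_products,
            "n_chemicals": self.n_chemicals,
            "n_years": self.n_years,
        }.items():
            if c < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {c}")
        if self.fields_per_farm_mean < 1:
            raise ConfigurationError("fields_per_farm_mean must be >= 1")
        if self.grid_cell_m <= 0 or self.storie_cell_m <= 0:
            raise ConfigurationError("grid sizes must be positive")


def _default_yield_gaps() -> dict[str, float]:
    # Synthetic placeholder multipliers (organic/conventional yield ratio) per
    # commodity group; real analyses should supply values from a meta-analysis
    # of their choice.  ``all_crops`` is the fallback for unmapped crops.
    return {
        "cereals": 0.75,
        "roots_tubers": 0.85,
        "oilseeds": 0.80,
        "legumes_pulses": 0.90,
        "fruits": 0.95,
        "vegetables": 0.90,
        "all_crops": 0.85,
    }


@dataclass
class TrueParams:
    """Parameters of the two-part spray/amount data-generating process.

    The spray decision is a probit in the covariates
    ``[1, organic, log field size, log farm size, storie]`` with a
    farm-by-crop-family random intercept of variance ``tau2_h1``; the amount
    sprayed, conditional on spraying, is lognormal with linear predictor
    ``x @ beta`` plus a group intercept of variance ``tau2_h2`` and residual
    log-variance ``sigma2``.
    """

    gamma: tuple[float, ...] = (0.35, -0.85, 0.15, 0.05, -0.15)
    beta: tuple[float, ...] = (2.5, -0.10, 0.10, -0.05, -0.10)
    sigma2: float = 1.5
    tau2_h1: float = 0.25
    tau2_h2: float = 0.25
    #: If True the two hurdles share one group intercept draw per group.
    correlated_intercepts: bool = False
    yield_gap_table: dict[str, float] = field(default_factory=_default_yield_gaps)

    def validate(self) -> None:
        if self.sigma2 < 0:
            raise ConfigurationError("sigma2 must be >= 0")
        if self.tau2_h1 < 0 or self.tau2_h2 < 0:
            raise ConfigurationError("random-intercept variances must be >= 0")
        if len(self.gamma) != 5 or len(self.beta) != 5:
            raise ConfigurationError("gamma and beta must have 5 entries")
        for k, m in self.yield_gap_table.items():
            if m <= 0:
                raise ConfigurationError(f"yield gap multiplier for {k} must be > 0")


#: Pesticide-use outcome classes carried through metrics and models.
OUTCOMES = ("ai", "product", "insecticide", "drift", "fish", "bee", "high_tox", "low_tox")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate → identify → metrics → fit)."""

    sim: SimConfig = field(default_factory=SimConfig)
    params: TrueParams = field(default_factory=TrueParams)
    buffer_m: float = 50.0
    top_n: int = 50
    idw_power: float = 2.0
    pti_threshold: float = 0.7
    outcomes: tuple[str, ...] = OUTCOMES
    #: Crops refit individually (year random intercepts, HC-robust SEs).
    focal_crops: tuple[str, ...] = ("carrot", "grape", "orange", "potato", "onion")
    fit_crop_specific: bool = True
    apply_yield_gap: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.params.validate()
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")
        if not 0 < self.pti_threshold <= 1:
            raise ConfigurationError("pti_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        params = raw.pop("params", {})
        for key in ("gamma", "beta"):
            if key in params:
                params[key] = tuple(params[key])
        cfg = cls(sim=sim, params=TrueParams(**params), **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
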