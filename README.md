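# orgfield

Identify certified-organic crop fields from messy registry, parcel and
pesticide-use data, and estimate how organic management changes pesticide use
with lognormal double-hurdle models — exercised end to end on a fully
synthetic county so every stage is testable without any restricted dataset.

## Who this is for

Field-level pesticide-use records (e.g. California Pesticide Use Reports) and
organic-certification registries exist, but they do not share keys: the
registry reports free-text Assessor's Parcel Numbers (APN) or Public Land
Survey Township-Range-Section (TRS) strings, while use reports are keyed by
grower permit, site and year. Researchers who want to compare pesticide use
on organic versus conventional fields must (1) repair and link those
identifiers, (2) refine the resulting candidate set against the pesticide
products actually applied, (3) build per-field use-rate and hazard metrics,
and (4) model the two-part outcome — whether a field is sprayed at all, and
how much it receives if it is. `orgfield` packages all four stages, plus a
synthetic data generator that emulates the whole data structure with known
ground truth, so the pipeline's recovery properties can be measured exactly.

## The model

Pesticide use per hectare `y` on a field is modeled as a double hurdle.
The spray decision is a probit with a farm-by-crop-family random intercept
`u_g ~ N(0, τ₁²)`:

    P(y = 0 | x) = 1 − Φ(x'γ + u_g)

and the amount sprayed, conditional on spraying, is lognormal with its own
group intercept `v_g ~ N(0, τ₂²)`:

    log(y) | x, y > 0  ~  Normal(x'β + v_g, σ²)

where `x = [1, organic, log field size, log farm size, soil grade]`. The
random intercepts are integrated out with Gauss–Hermite quadrature (hurdle 1)
or profiled in closed form (hurdle 2); inference uses cluster-robust sandwich
variances at the same grouping. Reported effects are the discrete-change
average marginal effect (AME) of the organic indicator from hurdle one and
the semi-elasticity `100(e^β − 1)` (delta-method SE `100·e^β·se`) from hurdle
two. Yield-gap adjustment multiplies organic rates by a per-crop-group
factor, which provably leaves hurdle one untouched and shifts the hurdle-two
organic coefficient by exactly the log multiplier.

## Worked example

```bash
orgfield all --seed 1 --outdir run
orgfield fit --outdir run --outcome product
orgfield fit --outdir run --outcome high_tox
```

prints

```
identification precision=1.000 recall=1.000; report in run/report.json
outcome product: AME(organic) = -0.297 (SE 0.050); semi-elasticity = -21.1% (SE 11.7)
outcome high_tox: AME(organic) = -0.280 (SE 0.024); semi-elasticity = -7.7% (SE 30.7)
```

Reading: on the default synthetic county (150 farms, ~2,300 field-years,
default registry corruption), every certified-organic field planted by the
generator was recovered exactly (precision = recall = 1.0). Being organic
reduces the probability of applying any pesticide product by about 30
percentage points, while fields that do spray show a statistically weak ~21%
reduction in product mass per hectare — the same qualitative two-part pattern
the model family was designed to expose. Per-stage artifacts (candidate
sets, match and refinement audits, the analysis table, per-outcome effect
tables, a management-class summary) are written under `run/`.

The library surface mirrors the stages: `orgfield.synthetic` (generator),
`orgfield.harmonization` (`clean_apn`, `clean_trs`, `buffered_field_join`),
`orgfield.refinement` (`refine_organic`), `orgfield.metrics`
(`build_analysis_table`, `idw_impute`, `pti_fish`), and `orgfield.hurdle`
(`fit_double_hurdle`, `ame_organic`, `semi_elasticity`, `apply_yield_gap`,
`fit_panel_ancillary`).

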