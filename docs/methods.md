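# Methods

This note documents the models, algorithms and design choices behind
`orgfield`, in the order the pipeline runs them.

## 1. Synthetic data generator

The generator produces every input the identification and analysis stages
consume, from one seed, with planted ground truth.

**Landscape.** Survey sections are square cells (default 1,600 m edge) on a
planar meter grid; tax parcels are section quadrants; crop fields are
axis-aligned rectangles obtained by guillotine splits of a parcel, with a
minimum side of ~120 m so that no field lies entirely inside the 50 m
erosion margin used by the spatial join. Each parcel belongs to exactly one
farm and the number of fields per parcel is driven by a lognormal target
field area (default mu = 2.7, sigma = 0.6 in log-hectares, i.e. a median
field of ~15 ha). Fields persist across years (default 3); perennial crops
keep their crop, annual crops rotate, and a configurable share (default 5%)
of field-years carry two crops under distinct site ids.

**Soil.** A soil-productivity grade surface (integer grades 1 best … 6
unproductive) is generated as a Gaussian-smoothed random field rasterized at
60 m, scaled to mean ≈ 1.8 and clipped to the grade range, with one
rectangular missing blob (default 2% of cells) to exercise imputation.

**Management.** Organic status is assigned at the farm level. With
adoption share `p` and correlation knobs `c_size`, `c_soil`, a farm is
organic with probability `Φ(Φ⁻¹(p) + c_size·z(log farm area) −
c_soil·z(mean soil grade))`; both knobs at zero give exact independent
Bernoulli(p) draws. Defaults (p = 0.08, c_size = 0.6, c_soil = 0.3) emulate
a county where organic fields are a ~10% minority concentrated on larger
farms and better soil.

**Products.** The catalog (default 300 products) carries a type (incl.
dual-action and adjuvant-only), an active-ingredient chemical code and mass
fraction (Uniform(0.1, 1); 0 for adjuvant-only), hazard flags (fish, bee,
aquatic, drift), an acute-toxicity signal word, and the *evidence* a reviewer
would use to classify it: organic label wording, an OMRI listing, or fully
known organic ingredients. True-organic products receive one of the three
evidence routes (77/22/1%, matching the relative frequency of the routes in
real hand-classification); conventional products receive none. By default
organic products carry hazard flags and toxic signal words less often than
conventional ones; `hazard_differs_by_class=False` equalizes the profiles,
which is the correct sharp-null configuration for placebo checks — with
differing profiles, class-specific outcomes inherit a genuine composition
effect even when the spray parameters contain no organic term.

**Two-part process.** With design `x = [1, organic, log adjusted area,
log farm size, soil grade]` and farm-by-crop-family intercepts
`u_g ~ N(0, τ₁²)`, `v_g ~ N(0, τ₂²)` (independent across hurdles by default,
sharable via a toggle):

* spray ~ Bernoulli(Φ(x'γ + u_g));
* conditional on spraying, total product mass per hectare is
  LogNormal(x'β + v_g, σ²), split across 1 + Poisson(1) application events
  with Dirichlet shares.

Organic fields draw products exclusively from the organic-classified subset;
conventional fields draw from the full catalog. Default parameters
(γ = (0.35, −0.85, 0.15, 0.05, −0.15), β = (2.5, −0.1, 0.1, −0.05, −0.1),
σ² = 1.5, τ² = 0.25 each) put the conventional spray share near 0.75 and the
organic spray-probability gap near −0.30 — the regime the model family is
meant for: a strong extensive-margin effect and a weak intensive-margin one.
`calibrate_organic_gamma` root-finds the organic coefficient that produces an
exact target average marginal effect over a realized covariate pool.

**Registry corruption.** One registry row per organic farm-year. APN rows
pack all the farm's parcel numbers into one free-text cell with mixed
separators (newline/semicolon/comma/space); each token suffers at most one
corruption: leading-zero stripping, right-appended digits, dash removal, a
spurious fourth segment (all repairable by the cleaning rules), or digit
truncation below eight characters (deliberately unrepairable — such tokens
must be dropped). TRS rows add "T"/"R"/"S"/"Sec." prefixes and unpad the
section number. The TRS reporting share defaults to zero: a section contains
fields of several farms, so section-level location is inherently ambiguous
and exact truth recovery is only possible through the parcel route. Raising
`registry_trs_share` demonstrates the resulting misidentification in the
pipeline's confusion matrix.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real county shapefile dialects and geometry errors,
temporal within-season application dynamics, crop-portfolio differences
between organic and conventional growers (the synthetic crop mix is
management-independent), economic crop choice, parent-company structure
behind permits, and non-random missingness of toxicity data.

## 2. Identifier harmonization

APN repair applies, in order: strip non-digit/non-dash characters; insert
dashes after the 3rd, 6th and 8th characters of a dashless token (tokens with
fewer than eight digits and no dashes are dropped outright); pad each of the
first two segments left with zeros to width 3 and the third to width 2, or
trim from the right when over-wide; drop segments beyond the third but keep
them in the provenance trail. The transformation is idempotent, and every
applied fix is counted in the match report, whose totals reconcile exactly
(matched + unmatched + dropped = records). TRS repair strips
"T"/"R"/"S"/"Sec."/"Section" prefixes case-insensitively, zero-pads the
section to two digits and concatenates (e.g. `29S26E07`); the concatenated
key format is this package's canonical choice.

Matched parcels are linked to fields by an inward buffer: each parcel is
eroded by 50 m (a parameter) and a field joins if it intersects the eroded
polygon, which removes fields merely touching the parcel margin. Polygons
that vanish under erosion are excluded and logged. The join predicate is
intersection rather than containment, so the candidate set shrinks weakly as
the buffer grows.

## 3. Iterative refinement

Products used on candidate fields are classified in batches of the `top_n`
(default 50) most-applied unclassified products — ties broken by product id —
via the evidence cascade: organic label wording → OMRI listing → fully known
organic ingredients → conventional by conservative default (which also
covers inactive or unresolvable products). Candidates that applied any
conventionally classified product are eliminated; the loop re-ranks after
each batch and stops when every product on the surviving candidates is
classified, which bounds iterations by ⌈n_products / top_n⌉ + 1. Final
labels: surviving sprayed candidates are organic; zero-pesticide candidates
keep their registry flag; zero-pesticide non-candidates and everything else
are conventional; fields outside the candidate set are never promoted. When
the catalog is fully classified the result is provably independent of
`top_n` and equals direct brute-force labeling (tested for top_n ∈ {1, 5,
50}).

## 4. Metrics

Multi-crop field-years split area equally among the crops sharing the
geometry (total area conserved exactly). Use rates are mass / adjusted area:
active-ingredient mass for the AI outcome, product mass for the total and
for every hazard class — product mass deliberately, because adjuvant-only
products can carry hazards despite zero AI. Insecticide use counts
insecticides, insect-growth regulators, miticides and repellents, excluding
dual-action (insecticide + fungicide) products but not insecticides with
additive ingredients. High acute human toxicity is signal word 1–2, low is
3, 4 or not required.

Soil grades are extracted per field as the area-weighted mean of overlapped
raster cells (missing cells carry no weight; a field over only missing cells
is missing). Missing fields are imputed by inverse-distance weighting from
field centroids, `w_i = d_i^(-power)` with power 2 by default (the power and
neighborhood are parameters, as no canonical value exists), exact at
coincident points; accuracy is reported as leave-one-out RMSE over up to 500
random known points. Model stages drop imputed-soil and missing-family rows
by default and count them.

The fish Pesticide Toxicity Index is Σ (AI use rate / fish toxicity value)
over matched chemicals. Use rate (kg/ha) stands in for ambient
concentration — a documented departure from concentration-based indices,
acceptable for relative comparisons only. Coverage is the count fraction of
distinct AIs with toxicity data (per field, not mass-weighted); fields below
the 0.7 default threshold are flagged for exclusion.

## 5. Double-hurdle estimation

**Hurdle 1** is a random-intercept probit fitted by maximum likelihood. The
group intercept is integrated with a plain (non-adaptive) Gauss–Hermite rule,
default 20 nodes: at the group sizes generated here (a handful to a few dozen
observations) the plain rule is already accurate, which the node-stability
test quantifies (|Δ log L| < 1e-6 between 20 and 30 nodes); adaptivity was
judged not worth its complexity at this scale. Group scores are analytic;
optimization is L-BFGS-B (τ bounded at zero) followed by a Newton polish on a
finite-difference Hessian that drives the gradient below 1e-10, so
closed-form identities (e.g. the saturated-model AME) hold to 1e-6 or
better. τ = 0 reduces the likelihood exactly to the plain probit. Estimated
τ landing on the boundary triggers a re-polish with τ pinned at zero.
Degenerate outcomes raise a separation error; rank-deficient designs raise
an error naming the collinear columns.

**Hurdle 2** is a random-intercept linear model on log outcome, ML (not
REML). With λ = τ²/σ² fixed, the GLS coefficients and ML residual variance
are closed-form via the Woodbury identity on the intra-group
equicorrelation, so estimation is a 1-D bounded search over log λ with an
explicit λ = 0 boundary check; λ = 0 reproduces OLS exactly.

**Inference.** Cluster-robust sandwich `A⁻¹ (Σ_g s_g s_g') A⁻¹` with
small-sample factor G/(G−1) and normal critical values, clustered at the
random-intercept grouping (the software default small-sample convention
differs across packages; G/(G−1) is used consistently here). For
heteroskedasticity-robust ("HC") variants the per-cluster scores are replaced
by per-observation score contributions — for the mixed models these are the
posterior-weighted within-group summands, which sum exactly to the group
scores and reduce to the classic HC scores when τ = 0. Only the coefficient
block of the covariance is reported; in hurdle 2 the bread is block-diagonal
between coefficients and variance parameters, so the within-group split of
the variance-parameter scores cannot affect reported SEs.

**Effects.** The organic AME is the discrete difference
`mean[Φ(x'γ|org=1) − Φ(x'γ|org=0)]` with the random intercept at zero
(conditional scale); a population-averaged option rescales the index by
`1/√(1+τ²)`. The default matches the conditional coefficients the model
reports; the population-averaged version is the one comparable to raw
marginal spray-share differences when τ² is large. SEs are delta-method
against the cluster-robust coefficient covariance. The hurdle-2 organic
effect is reported as the semi-elasticity `100(e^β − 1)` with analytic
delta-method SE `100·e^β·se`.

**Crop-specific fits** re-run both hurdles within one crop with year random
intercepts and HC-robust SEs; a crop observed in fewer than two years falls
back to no intercept with a warning. **Yield-gap adjustment** multiplies
organic rows' rates by a per-crop-group factor with an `all_crops` fallback.
The shipped default multipliers are synthetic placeholders — real analyses
must supply values from a meta-analysis of their choosing. Because the
factors are positive, spray indicators are unchanged and the hurdle-1 fit is
bit-identical; on the log scale the organic coefficient shifts by exactly
ln m in the single-group case, i.e. `(1 + s_new/100) = m (1 + s_old/100)` for
the semi-elasticity.

**Ancillary panel models** (pooled OLS, within estimator by group-mean
differencing, random effects by the same ML machinery) operate on
IHS-transformed outcomes, `arcsinh(100·y)` — log-like but defined at zero,
with the ×100 pre-multiplication improving the log approximation at small
rates — and report AIC/BIC for specification comparison.

## 6. Pipeline and reproducibility

One global seed is fanned out to per-stage child seeds through
`SeedSequence(seed, crc32(stage))`, so stages are independently reproducible
and a rerun is bit-identical (tested at the byte level on the report and the
analysis table). Every stage writes plain-text artifacts; a stage failure
aborts with the stage name, keeping completed artifacts on disk. Dropped
rows (missing family, imputed soil) are counted and reconciled against the
table size.

Default problem sizes — 150 farms (~2,300 field-years) for the end-to-end
study, 5,000 fields × 200 replicates for the coverage study, 20,000 fields
for effect recovery — were chosen as the smallest scales at which the
Monte-Carlo error of each check is comfortably below its tolerance.

## Known limitations

* The synthetic landscape is rectangular and gap-free; it cannot probe
  robustness to sliver polygons, invalid geometries or datum mismatches.
* HC-robust inference for the mixed models uses the posterior-weighted
  observation-level score decomposition described above; it is a working
  convention, not an established small-sample-exact estimator.
* The AME integrates the random intercept at zero by default; with large τ²
  this conditional effect exceeds the population-averaged one in magnitude.
* The PTI uses use-rate as the exposure proxy and a synthetic toxicity
  table; absolute index values are not comparable to concentration-based
  published indices.
* Organic/conventional crop portfolios are identical in distribution, so the
  farm-by-crop-family grouping is exercised structurally but compositional
  confounding between crop choice and management is not simulated.
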