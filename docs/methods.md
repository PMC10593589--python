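# Methods

## PhenoAge scoring

PhenoAge converts a 10-year Gompertz mortality risk into an age scale.
The linear predictor `xb` combines chronological age and 9 biomarkers
with fixed published coefficients; `M = 1 − exp(−1.51714·e^xb/0.0076927)`
is the implied mortality probability; the outer transform re-expresses
`M` as the chronological age at which an average person carries the same
risk. The scale factor satisfies `1.51714 = e^{120·0.0076927} − 1`, which
identifies the expression as a Gompertz CDF and fixes the reading of the
mortality equation as a *division* by the rate constant 0.0076927.

Conventions and assumptions:

* **Units** (the published equation omits them): albumin g/L, creatinine
  µmol/L, glucose mmol/L, CRP mg/dL (entered as natural log), lymphocyte
  percent 0–100, MCV fL, RDW %, ALP U/L, WBC 10³ cells/µL, age years.
  The column dictionary exposes these so users can convert upstream.
* **CRP floor**: CRP ≤ 0 is floored to 0.01 mg/dL before the log
  (configurable), motivated by assay detection limits.
* **Denominator constant**: the default is 0.09165 as used in the analysis
  this package operationalizes; the original PhenoAge derivation uses
  0.090165. `PhenoAgeConstants(pheno_denom=0.090165)` switches variants.
* **Inverse**: algebraically `xb = 0.09165·(P − 141.50) + ln(γ/(0.00553·1.51714))`,
  an affine map. The forward/backward round trip is exact to ≤1e−9 years
  for PhenoAge up to roughly 110 years; beyond that `M` saturates in
  float64 and the composed chain loses precision. Targets that would
  overflow `e^xb` raise a domain error.
* PhenoAge is treated as a continuous outcome throughout; the
  `age_accel` column (PhenoAge − age) is a convenience only.

## DII scoring

Each nutrient intake is standardized against a global reference mean and
SD, mapped to the centered percentile `2·Φ(z) − 1 ∈ (−1, 1)`, weighted by
the nutrient's signed inflammatory effect score, and summed. Missing
nutrients contribute zero (the count used is reported per record), which
matches the index's tolerance for incomplete parameter sets; negative
intakes are rejected rather than clamped. The 26-nutrient reference table
(means, SDs, effect scores, 2014 revision of the literature-derived
index) ships as a versioned CSV with a SHA-256 checksum recorded in run
metadata; every numerical test of the algorithm uses toy tables so the
algorithm is verified independently of the transcription. Diets are
dichotomized at zero with the boundary assigned to pro-inflammatory.
No energy-density adjustment is applied to the DII; energy instead enters
the fully adjusted model as a covariate.

## Survey-weighted inference

Point estimates are weighted least squares (statsmodels WLS behind the
module surface). Variances use Taylor linearization under the
with-replacement PSU approximation: per-record score contributions
`w·e·x` are totaled by PSU, and the between-PSU variability within each
stratum, scaled by `n_h/(n_h − 1)`, is sandwiched with `(XᵀWX)⁻¹`. Design
df = #PSUs − #strata; CIs and p-values use the t distribution with that
df because subgroup fits can leave few PSUs. Joint hypotheses use
`F = (βₛᵀVₛ⁻¹βₛ)/q` against `F(q, df − q + 1)`.

Numerical and edge-case conventions:

* β and the covariance are invariant to global weight rescaling
  (asserted to 1e−10 in tests), so multi-cycle weight constructions
  (divide cycle weights by the number of cycles pooled) never change
  estimates.
* Rank-deficient design matrices raise an error naming the collinear
  columns (QR with pivoting).
* Strata reduced to a single PSU by subsetting are scored against the
  grand mean of PSU totals with a warning ("centered" rule); a strict
  mode raises instead.
* Interaction tests for a 3-level modifier are joint Wald tests on both
  product terms (q = 2), one p per modifier; a single-term t-test variant
  is available for binary modifiers.
* Categorical terms are dummy-coded against declared reference levels;
  product terms multiply coded columns. This is done directly in pandas
  for deterministic column naming.

## Cohort pipeline

The exclusion cascade applies, in order: age < 20; any missing PhenoAge
biomarker; missing diet (any nutrient or energy); missing covariates;
implausible reported energy (< 500 kcal/day, or > 5,000 for women /
8,000 for men — a common recall-plausibility convention, configurable).
Each step logs removed and remaining counts.

Weighted descriptives use a deterministic non-interpolating quantile
(smallest value whose cumulative normalized weight ≥ p); an interpolating
variant exists. Categorical rows report unweighted counts with weighted
percentages. The univariate screen fits one single-predictor model per
variable. The nested models share the diet contrast as exposure: model 1
adjusts age (continuous by default; age bands by option) and sex; model 2
adds race and BMI; model 3 adds energy, smoking, drinking, exercise,
education and the income-to-poverty ratio. Stratified fits drop the
stratifier (and its continuous counterpart: bands displace continuous age
or BMI) from the adjustment set; the per-stratifier interaction p comes
from the full-data model plus modifier main effects and diet×modifier
products. Levels with no design df are flagged, never dropped.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with exact
ground truth:

1. 15 strata × 2 PSUs, records assigned uniformly; lognormal(0, 0.5)
   weights.
2. Age ~ 20 + 65·Beta(1.194, 1.686), which places 38.9 / 44.3 / 16.8% of
   adults in the 20–39 / 40–64 / ≥65 bands — the published band shares of
   the survey years this emulates (the Beta shapes are solved from those
   two published proportions). Covariate category probabilities follow
   the same descriptive table.
3. A latent diet factor `u` (intercept −0.55, tuned so about half the
   cohort is pro-inflammatory) with confounding channels: female sex,
   non-white race, age, BMI, current smoking, lower education and lower
   income shift `u` upward/downward with documented loadings. Nutrient
   z-scores load on `u` with the sign of each nutrient's effect score
   (|λ| = 0.6) plus N(0, 0.8) noise; intakes are mean + SD·z truncated
   at zero. DII and diet class are computed forward from the emitted
   intakes, and energy is assembled from the macronutrients with Atwater
   factors — so every derived quantity is self-consistent.
4. The target PhenoAge is built explicitly: age − 6 + β_diet·pro +
   β_int·band·pro + linear covariate effects + PSU random effect
   N(0, 1) + N(0, residual SD). The default residual SD is 5 years,
   matching the documented spread of PhenoAge acceleration in US survey
   adults (and consistent with the narrow excess of the published
   PhenoAge IQR over the age IQR). The exact inverse then yields the
   required `xb`, and RDW — the marker with the largest coefficient — is
   solved linearly to hit it while the other biomarkers sit at fixed
   reference values.

Implanting the effect on PhenoAge and inverting exactly (rather than
shifting biomarkers) makes the true regression coefficient a known
number: forward-scoring the emitted biomarkers reproduces the target to
machine precision, and every parameter-recovery test is sharp. The PSU
random effect guarantees that design-based SEs genuinely exceed naive
ones, exercising the Taylor variance path. Optional clamping rejects
records whose targets would need RDW outside 9–25% (off by default,
favoring exactness).

What the generator does **not** emulate: realistic marginal biomarker
distributions (all markers except RDW are constant), measurement error in
24-hour recalls, item-level nutrient correlation beyond one factor, and
oversampling structure in the weights. Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated model,
not robustness to those real-data features.

## Calibration checks and problem sizes

`scripts/acceptance.py` runs 200 cohorts of n = 5,000 per setting (a few
minutes on one CPU): mean recovered diet coefficient under the fully
adjusted model (truth 0.73 y), under the age/sex model on confounder-free
cohorts (truth 1.78 y), under the age/sex/race/BMI model (truth 1.38 y),
and the 95th percentile of the joint diet×age-band interaction p when the
implanted interaction is 1.5 y per band. The test suite runs
reduced-size renditions of the same checks (60 cohorts of n = 2,000 for
recovery; 50 replicates at n = 5,000 for interaction detection; 500
cohorts of n = 1,000 for CI coverage), chosen to keep the default suite
fast while leaving Monte-Carlo tolerances meaningful.

Known limitation: with the default 15-stratum/30-PSU design the design df
is 15, so the joint interaction test compares against F(2, 14), whose
0.001-level critical value is large (~11.8). At the 1.5 y/band effect
size, detection at p < 0.001 runs at ~91% of replicates rather than ≥95%;
the analogous pooled multi-cycle design of the real survey (df ≈ 80–90)
would detect essentially always. Detection at p < 0.05 is 100%.

## Determinism

Every stochastic component is driven by one `numpy` Generator seeded from
the config; missingness masking derives its stream from the same seed.
Fixed input plus fixed configuration gives byte-identical output tables
(floats are written with shortest exact decimals and re-parsed with exact
`strtod`).
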