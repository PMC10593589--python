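# phenodii

Tools for studying **dietary inflammation and biological aging** in
complex-survey cohorts: phenotypic age (PhenoAge) scoring from routine
clinical chemistry, the dietary inflammatory index (DII) from daily
nutrient intakes, design-based weighted linear regression with
Taylor-linearized variance for stratified clustered samples (NHANES-style
pseudo-stratum / pseudo-PSU designs), and a synthetic cohort generator
with exactly known ground truth so the whole pipeline is testable without
downloading any survey files.

It is aimed at epidemiologists and biostatisticians who want a
reproducible, scriptable version of the familiar analysis arc: score a
cohort, run an exclusion cascade, produce weighted descriptives, fit
nested adjusted models with a pro- vs anti-inflammatory diet contrast as
the exposure, and probe effect modification with stratified fits and
interaction tests.

## The models

**PhenoAge** maps chronological age and 9 biomarkers (albumin, creatinine,
glucose, ln CRP, lymphocyte %, mean cell volume, red-cell distribution
width, alkaline phosphatase, white cell count) to a years scale through a
Gompertz mortality model:

    xb       = −19.907 − 0.0336·albumin + 0.0095·creatinine + 0.1953·glucose
               + 0.0954·ln(CRP) − 0.0120·lymphocyte% + 0.0268·MCV
               + 0.3306·RDW + 0.00188·ALP + 0.0554·WBC + 0.0804·age
    M        = 1 − exp(−1.51714 · e^xb / 0.0076927)
    PhenoAge = 141.50 + ln(−0.00553 · ln(1 − M)) / 0.09165

The chain is analytically invertible (`invert_phenoage` is affine in the
target), which the simulator exploits to implant exact effects.

**DII** sums, over 26 nutrients, the nutrient's inflammatory effect score
times the centered percentile `2·Φ(z) − 1` of the intake z-score against a
global reference mean/SD. DII < 0 is an anti-inflammatory diet; DII ≥ 0
pro-inflammatory.

**Inference** is survey-weighted least squares with the with-replacement
PSU approximation: per-stratum between-PSU variability of weighted score
totals, sandwiched with (XᵀWX)⁻¹; t inference on design degrees of freedom
(#PSUs − #strata); joint Wald F tests for interactions.

## Worked example

```python
from phenodii import GeneratorConfig, generate_cohort, pipeline

records, truth = generate_cohort(GeneratorConfig(n=5000, seed=1, beta_diet=0.73))
bundle = pipeline.run_all(records)
fit = bundle["model_fits"]["model_3"]
print(fit.term_row(pipeline.DIET_TERM)[["beta", "ci_low", "ci_high", "p"]])
```

prints (seed 1):

```
beta       0.931729
ci_low     0.495897
ci_high    1.367562
p          0.000378
```

i.e. in this replicate the fully adjusted model estimates that a
pro-inflammatory diet adds 0.93 years of PhenoAge (95% CI 0.50–1.37),
covering the implanted truth of 0.73 years. The same analysis is available
from a shell:

```bash
phenodii simulate --n 5000 --seed 1 --out cohort.csv
phenodii run-all --input cohort.csv --out results/ --seed 1
```

which writes the exclusion log, weighted descriptives by diet class, the
univariate screen, the three nested adjusted models, the stratified forest
table with per-stratifier interaction p-values, and run metadata.

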