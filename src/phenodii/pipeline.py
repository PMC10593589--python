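"""End-to-end cohort analysis: exclusions, recoding, descriptives, models.

The pipeline reproduces the shape of a typical complex-survey dietary
analysis: an ordered exclusion cascade with a per-step log, covariate
recoding into the standard three-level categories, survey-weighted
descriptive statistics by diet class, a univariate screen, three nested
adjusted models with the pro- vs anti-inflammatory diet contrast as the
exposure, and a stratified analysis with per-stratifier interaction tests
(the data table behind a forest plot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phenodii import dii as dii_mod
from phenodii import phenoage as pa
from phenodii.survey import (
    ModelFit,
    ModelSpec,
    SurveyDesign,
    SurveyError,
    Term,
    design_df,
    fit_survey_model,
    wald_test,
)

__all__ = [
    "ExclusionParams",
    "PipelineError",
    "recode_covariates",
    "score_cohort",
    "apply_exclusions",
    "weighted_quantile",
    "build_table1",
    "run_univariate",
    "run_adjusted_models",
    "stratified_forest",
    "run_all",
    "DIET_TERM",
    "MODEL_TERMS",
    "STRATIFIERS",
]

COVARIATE_COLS = [
    "sex",
    "race",
    "education",
    "income_poverty_ratio",
    "exercise",
    "smoking",
    "drinking",
    "bmi",
]

#: Coefficient label of the exposure contrast in every fitted model.
DIET_TERM = "diet_class[pro_inflammatory]"


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ExclusionParams:
    """Tunable rules of the exclusion cascade.

    The plausibility window on reported daily energy follows the common
    dietary-recall convention: below 500 kcal, or above 5,000 kcal for
    women / 8,000 kcal for men, counts as extreme.
    """

    min_age: float = 20.0
    energy_min: float = 500.0
    energy_max_female: float = 5000.0
    energy_max_male: float = 8000.0


def recode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived categories: bmi_group, age_group, smoking, drinking.

    BMI: under/healthy < 25.0 ≤ overweight < 30.0 ≤ obese (kg/m²).
    Age bands: 20–39, 40–64, ≥65.  If the three-level smoking / drinking
    statuses are absent but raw instrument fields are present
    (``cigs_lifetime``, ``cigs_per_day_30d``; ``drinks_lifetime``,
    ``drinks_past_year``, ``drinks_per_week``), they are derived here:
    fewer than 100 lifetime cigarettes → non-smoker, fewer than 12
    lifetime drinks → non-drinker, with former/current split by current
    use.  Unclassifiable raw values become missing (flagged for the
    exclusion cascade).
    """
    out = df.copy()
    bmi = out["bmi"].to_numpy(dtype=float)
    out["bmi_group"] = np.select(
        [bmi < 25.0, bmi < 30.0], ["under_healthy", "overweight"], default="obese"
    )
    out.loc[~np.isfinite(bmi), "bmi_group"] = None
    age = out["chron_age"].to_numpy(dtype=float)
    out["age_group"] = np.select(
        [age < 40.0, age < 65.0], ["20_39", "40_64"], default="65_plus"
    )
    out.loc[~np.isfinite(age), "age_group"] = None

    if "smoking" not in out.columns and "cigs_lifetime" in out.columns:
        lifetime = out["cigs_lifetime"].to_numpy(dtype=float)
        per_day = out.get("cigs_per_day_30d", pd.Series(np.zeros(len(out)))).to_numpy(dtype=float)
        smoking = np.where(
            lifetime < 100.0, "non", np.where(per_day > 0.0, "current", "former")
        ).astype(object)
        smoking[~np.isfinite(lifetime)] = None
        out["smoking"] = smoking
    if "drinking" not in out.columns and "drinks_lifetime" in out.columns:
        lifetime = out["drinks_lifetime"].to_numpy(dtype=float)
        past_year = out["drinks_past_year"].to_numpy(dtype=float)
        per_week = out.get("drinks_per_week", pd.Series(np.zeros(len(out)))).to_numpy(dtype=float)
        drinking = np.where(
            lifetime < 12.0,
            "non",
            np.where(past_year < 12.0, "former", np.where(per_week > 0.0, "current", None)),
        ).astype(object)
        drinking[~np.isfinite(lifetime)] = None
        out["drinking"] = drinking
    return out


def score_cohort(
    df: pd.DataFrame,
    params: dii_mod.DIIParameterTable | None = None,
    crp_floor: float = pa.DEFAULT_CRP_FLOOR,
) -> pd.DataFrame:
    """Derive phenoage, dii, diet_class and recoded groups for a cohort."""
    if params is None:
        params = dii_mod.load_dii_parameters()
    out = pa.score_table(df)
    out = dii_mod.score_dii_table(out, params)
    return recode_covariates(out)


def apply_exclusions(
    df: pd.DataFrame,
    params: ExclusionParams = ExclusionParams(),
    nutrient_prefix: str = "nut_",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential exclusion cascade with a per-step log.

    Steps, in order: age below 20 (or missing); any missing PhenoAge
    biomarker; missing diet (any nutrient or energy); missing covariates;
    extreme reported energy.  Returns the analysis cohort and a log frame
    with columns (step, rule, removed, remaining).
    """
    nut_cols = [c for c in df.columns if c.startswith(nutrient_prefix)]
    if not nut_cols:
        raise PipelineError("no nutrient columns found")
    bio_cols = list(pa.BIOMARKER_FIELDS) + ["chron_age"]

    steps: list[tuple[str, pd.Series]] = []
    age = pd.to_numeric(df["chron_age"], errors="coerce")
    steps.append(("age_under_20", age.isna() | (age < params.min_age)))
    steps.append(("missing_phenoage_biomarkers", df[bio_cols].isna().any(axis=1)))
    diet_missing = df[nut_cols].isna().any(axis=1) | df["energy"].isna()
    steps.append(("missing_diet", diet_missing))
    steps.append(("missing_covariates", df[COVARIATE_COLS].isna().any(axis=1)))
    energy = pd.to_numeric(df["energy"], errors="coerce")
    emax = np.where(df["sex"].astype(str) == "male", params.energy_max_male, params.energy_max_female)
    steps.append(("extreme_diet", (energy < params.energy_min) | (energy > emax)))

    current = df
    rows = []
    for i, (rule, mask) in enumerate(steps, start=1):
        drop = mask.loc[current.index].fillna(False)
        removed = int(drop.sum())
        current = current.loc[~drop]
        rows.append({"step": i, "rule": rule, "removed": removed, "remaining": len(current)})
    if current.empty:
        raise PipelineError("exclusion cascade removed every record")
    return current.reset_index(drop=True), pd.DataFrame(rows)


def weighted_quantile(values, weights, p: float) -> float:
    """Smallest observed value whose cumulative normalized weight ≥ p.

    A deterministic non-interpolating estimator; with equal weights it is
    the lower empirical quantile.  Set ``interpolate=True`` downstream via
    :func:`weighted_quantile_interp` if smoother medians are wanted.
    """
    if not 0.0 < p < 1.0:
        raise PipelineError(f"p must be in (0, 1), got {p}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise PipelineError("empty values")
    if np.any(w <= 0):
        raise PipelineError("weights must be positive")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cum, p, side="left"))
    return float(v[order][min(idx, v.size - 1)])


def weighted_quantile_interp(values, weights, p: float) -> float:
    """Interpolating variant of :func:`weighted_quantile` (Hazen-type)."""
    if not 0.0 < p < 1.0:
        raise PipelineError(f"p must be in (0, 1), got {p}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(p, cum, v))


CONTINUOUS_TABLE1 = ["chron_age", "income_poverty_ratio", "bmi", "energy", "phenoage"]
CATEGORICAL_TABLE1 = [
    "sex",
    "race",
    "age_group",
    "education",
    "exercise",
    "smoking",
    "drinking",
    "bmi_group",
]


def build_table1(df: pd.DataFrame, survey: SurveyDesign) -> pd.DataFrame:
    """Weighted descriptives overall and by diet class.

    Continuous variables: weighted median (p25, p75).  Categorical:
    unweighted count plus weighted percentage; percentages within a
    variable and group sum to 100.
    """
    if df["diet_class"].isna().any():
        raise PipelineError("diet_class must be derived before building Table 1")
    groups = {"total": np.ones(len(df), dtype=bool)}
    for cls in ("anti_inflammatory", "pro_inflammatory"):
        mask = (df["diet_class"].astype(str) == cls).to_numpy()
        if not mask.any():
            raise PipelineError(f"empty diet class {cls!r}")
        groups[cls] = mask
    w = survey.weight
    rows = []
    for var in CONTINUOUS_TABLE1:
        if var not in df.columns:
            continue
        for gname, mask in groups.items():
            v = df.loc[mask, var].to_numpy(dtype=float)
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "group": gname,
                    "n": int(mask.sum()),
                    "weighted_pct": np.nan,
                    "median": weighted_quantile(v, w[mask], 0.5),
                    "p25": weighted_quantile(v, w[mask], 0.25),
                    "p75": weighted_quantile(v, w[mask], 0.75),
                }
            )
    for var in CATEGORICAL_TABLE1:
        if var not in df.columns:
            continue
        levels = sorted(df[var].astype(str).unique())
        for gname, mask in groups.items():
            wtot = w[mask].sum()
            for level in levels:
                sel = mask & (df[var].astype(str) == level).to_numpy()
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "group": gname,
                        "n": int(sel.sum()),
                        "weighted_pct": 100.0 * w[sel].sum() / wtot,
                        "median": np.nan,
                        "p25": np.nan,
                        "p75": np.nan,
                    }
                )
    return pd.DataFrame(rows)


#: Univariate screen: (variable, kind, reference level or None).
UNIVARIATE_VARS: list[tuple[str, str, str | None]] = [
    ("diet_class", "categorical", "anti_inflammatory"),
    ("sex", "categorical", "female"),
    ("race", "categorical", "non_hispanic_white"),
    ("chron_age", "continuous", None),
    ("age_group", "categorical", "20_39"),
    ("education", "categorical", "under_high_school"),
    ("income_poverty_ratio", "continuous", None),
    ("exercise", "categorical", "inactive"),
    ("smoking", "categorical", "non"),
    ("drinking", "categorical", "non"),
    ("bmi", "continuous", None),
    ("bmi_group", "categorical", "under_healthy"),
    ("energy", "continuous", None),
]


def run_univariate(df: pd.DataFrame, survey: SurveyDesign) -> pd.DataFrame:
    """Single-predictor survey-weighted fits of PhenoAge, one per variable.

    Reference levels carry no estimate, mirroring the conventional
    "Reference" rows of a screening table.
    """
    rows = []
    for var, kind, ref in UNIVARIATE_VARS:
        if var not in df.columns:
            continue
        spec = ModelSpec(outcome="phenoage", terms=(Term(var, kind, ref),))
        fit = fit_survey_model(df, spec, survey)
        summ = fit.summary().set_index("term")
        if kind == "continuous":
            r = summ.loc[var]
            rows.append(
                {"variable": var, "level": "", "beta": r["beta"], "ci_low": r["ci_low"],
                 "ci_high": r["ci_high"], "p": r["p"]}
            )
        else:
            rows.append(
                {"variable": var, "level": ref, "beta": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan}
            )
            for label in summ.index:
                if label.startswith(f"{var}["):
                    r = summ.loc[label]
                    rows.append(
                        {"variable": var, "level": label[len(var) + 1 : -1],
                         "beta": r["beta"], "ci_low": r["ci_low"],
                         "ci_high": r["ci_high"], "p": r["p"]}
                    )
    return pd.DataFrame(rows)


def _model_terms(model: str, use_age_group: bool = False) -> tuple[Term, ...]:
    age_term = (
        Term("age_group", "categorical", "20_39") if use_age_group else Term("chron_age")
    )
    base = [Term("diet_class", "categorical", "anti_inflammatory"), age_term, Term("sex", "categorical", "female")]
    if model == "model_1":
        return tuple(base)
    base += [Term("race", "categorical", "non_hispanic_white"), Term("bmi")]
    if model == "model_2":
        return tuple(base)
    base += [
        Term("energy"),
        Term("smoking", "categorical", "non"),
        Term("drinking", "categorical", "non"),
        Term("exercise", "categorical", "inactive"),
        Term("education", "categorical", "under_high_school"),
        Term("income_poverty_ratio"),
    ]
    return tuple(base)


#: Adjustment sets of the three nested models (diet contrast is the exposure).
MODEL_TERMS = {m: _model_terms(m) for m in ("model_1", "model_2", "model_3")}


def run_adjusted_models(
    df: pd.DataFrame, survey: SurveyDesign, use_age_group: bool = False
) -> dict[str, ModelFit]:
    """Fit the three nested adjusted models.

    Model 1: age + sex.  Model 2: + race + BMI.  Model 3: + energy,
    smoking, drinking, exercise, education, income-to-poverty ratio.
    Continuous age is the default; set ``use_age_group`` to adjust for age
    bands instead.
    """
    fits = {}
    for model in ("model_1", "model_2", "model_3"):
        spec = ModelSpec(outcome="phenoage", terms=_model_terms(model, use_age_group))
        fits[model] = fit_survey_model(df, spec, survey)
    return fits


#: The seven stratifiers of the forest analysis, with the Model 3 term each
#: one displaces within levels (age bands displace continuous age, BMI
#: bands displace continuous BMI).
STRATIFIERS: dict[str, str | None] = {
    "sex": "sex",
    "age_group": "chron_age",
    "race": "race",
    "exercise": "exercise",
    "smoking": "smoking",
    "drinking": "drinking",
    "bmi_group": "bmi",
}


def stratified_forest(
    df: pd.DataFrame,
    survey: SurveyDesign,
    wald_joint: bool = True,
) -> pd.DataFrame:
    """Per-level diet effects plus one interaction p per stratifier.

    Within each level of a stratifier the fully adjusted model is refitted
    with the stratifier itself dropped from the adjustment set.  The
    interaction p comes from adding the modifier's main-effect dummies (if
    absent) and the diet×modifier product terms to the fully adjusted
    model on the full data and jointly Wald-testing the product terms
    (``wald_joint=False`` instead reports the single product-term t test,
    only defined for binary modifiers).  Levels whose subset leaves no
    design degrees of freedom are flagged, never silently dropped.
    """
    rows = []
    for strat, displaced in STRATIFIERS.items():
        terms = [t for t in MODEL_TERMS["model_3"] if t.name not in (strat, displaced)]
        # interaction model on the full data
        full_terms = list(MODEL_TERMS["model_3"])
        if strat not in [t.name for t in full_terms]:
            ref = sorted(df[strat].astype(str).unique())[0]
            full_terms.append(Term(strat, "categorical", ref))
        int_spec = ModelSpec(
            outcome="phenoage",
            terms=tuple(full_terms),
            interactions=(("diet_class", strat),),
        )
        int_fit = fit_survey_model(df, int_spec, survey)
        product_terms = [
            lbl for lbl in int_fit.params.index if lbl.startswith(f"{DIET_TERM}:{strat}[")
        ]
        if wald_joint or len(product_terms) > 1:
            p_int = wald_test(int_fit, product_terms)["p"]
        else:
            p_int = float(int_fit.term_row(product_terms[0])["p"])

        for level in sorted(df[strat].astype(str).unique()):
            mask = (df[strat].astype(str) == level).to_numpy()
            sub = df.loc[mask].reset_index(drop=True)
            subsurv = survey.subset(mask)
            row = {
                "stratifier": strat,
                "level": level,
                "n": int(mask.sum()),
                "beta": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "p_interaction": p_int,
                "flag": "",
            }
            try:
                design_df(subsurv)
                spec = ModelSpec(outcome="phenoage", terms=tuple(terms))
                fit = fit_survey_model(sub, spec, subsurv)
                r = fit.term_row(DIET_TERM)
                row.update(beta=r["beta"], ci_low=r["ci_low"], ci_high=r["ci_high"], p=r["p"])
            except SurveyError as exc:
                row["flag"] = f"not_estimable: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def run_all(
    df: pd.DataFrame,
    dii_params: dii_mod.DIIParameterTable | None = None,
    exclusion_params: ExclusionParams = ExclusionParams(),
    singleton: str = "center",
) -> dict[str, object]:
    """Raw cohort table → complete analysis bundle.

    Scores PhenoAge and DII, recodes covariates, applies the exclusion
    cascade, then produces the descriptive table, univariate screen, the
    three adjusted models and the stratified forest table.  Deterministic:
    fixed input and configuration give identical outputs.
    """
    if dii_params is None:
        dii_params = dii_mod.load_dii_parameters()
    scored = score_cohort(df, dii_params)
    cohort, log = apply_exclusions(scored, exclusion_params)
    survey = SurveyDesign.from_frame(cohort, singleton=singleton)
    fits = run_adjusted_models(cohort, survey)
    table3 = pd.concat(
        [
            fits[m].summary().assign(model=m)
            for m in ("model_1", "model_2", "model_3")
        ],
        ignore_index=True,
    )
    return {
        "cohort": cohort,
        "exclusion_log": log,
        "table1": build_table1(cohort, survey),
        "table2": run_univariate(cohort, survey),
        "table3": table3,
        "model_fits": fits,
        "forest": stratified_forest(cohort, survey),
        "dii_version": dii_params.version,
    }
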