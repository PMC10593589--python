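"""Synthetic survey cohorts with exactly known ground truth.

The generator emulates the structure a complex dietary survey analysis
assumes — a stratified design with two PSUs per stratum and unequal
lognormal weights, an adult age distribution over 20–85, demographic and
lifestyle covariates, and 26 correlated daily nutrient intakes driven by a
single latent diet-quality factor — while making the causal quantities of
interest exact rather than approximate:

* the latent factor ``u`` loads on each nutrient with the sign of that
  nutrient's inflammatory effect score, so high ``u`` means a
  pro-inflammatory diet; confounding channels shift ``u`` with covariates;
* each record's *target* PhenoAge is assembled explicitly (chronological
  age + baseline offset + diet effect + optional diet×age-band interaction
  + covariate effects + PSU random effect + Gaussian noise), then the exact
  analytic inverse of the PhenoAge chain yields the required linear
  predictor, and the red-cell distribution width — the marker with the
  largest coefficient — is solved linearly to hit it while all other
  biomarkers sit at fixed reference values.

Forward-scoring the emitted biomarkers therefore reproduces the target
PhenoAge to machine precision (clamping off), so the true regression
coefficient implanted in a cohort is a known number, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from phenodii import dii as dii_mod
from phenodii import phenoage as pa

__all__ = ["GeneratorConfig", "CohortTruth", "generate_cohort", "inject_missingness"]

#: Fixed reference values for every biomarker except rdw (solved per record).
REFERENCE_BIOMARKERS = {
    "albumin": 42.0,  # g/L
    "creatinine": 80.0,  # µmol/L
    "glucose": 5.3,  # mmol/L
    "crp": 0.2,  # mg/dL
    "lymphocyte_pct": 30.0,
    "mcv": 89.0,  # fL
    "alp": 70.0,  # U/L
    "wbc": 7.0,  # 10^3/µL
}

#: Plausible rdw window enforced only when clamping is requested.
RDW_PLAUSIBLE = (9.0, 25.0)

AGE_BANDS = ("20_39", "40_64", "65_plus")


def _default_covariate_effects() -> dict[str, float]:
    # Additive effects (years of PhenoAge) on top of chronological age;
    # continuous effects are per unit of the centered covariate.
    return {
        "sex_male": -0.5,
        "race_other": -3.0,
        "bmi": 0.4,  # per kg/m², centered at 28
        "energy": -0.0002,  # per kcal, centered at 2000
        "smoking_former": 2.0,
        "smoking_current": 1.0,
        "drinking_former": -1.0,
        "drinking_current": -1.5,
        "exercise_moderate": -1.0,
        "exercise_vigorous": -3.0,
        "education_high_school": -1.0,
        "education_college_or_above": -2.0,
        "income": -0.2,  # per income-to-poverty unit, centered at 2.5
    }


def _default_confounding() -> dict[str, float]:
    # Shifts of the latent diet factor u (pro-inflammatory positive).
    return {
        "sex_female": 0.5,
        "race_other": 0.4,
        "age_z": 0.10,  # per SD of age
        "bmi_z": 0.15,  # per SD of BMI
        "smoking_current": 0.3,
        "education_under_high_school": 0.4,
        "education_high_school": 0.2,
        "income_z": -0.25,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All true parameters of a synthetic cohort.

    ``beta_diet`` is the causal pro- vs anti-inflammatory contrast in years
    of PhenoAge; ``beta_age_interaction`` adds that many further years per
    older age band (20–39 → 0, 40–64 → 1, ≥65 → 2 bands).
    """

    n: int = 1000
    seed: int = 0
    # survey design
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_log_sd: float = 0.5
    # demographics
    # Beta shape calibrated so the 20–39 / 40–64 / ≥65 band masses are
    # 38.9 / 44.3 / 16.8 %, the adult distribution of the survey years
    # this generator emulates.
    age_beta: tuple[float, float] = (1.194031, 1.685526)
    age_range: tuple[float, float] = (20.0, 85.0)
    p_female: float = 0.5
    p_race_other: float = 0.3
    education_probs: tuple[float, float, float] = (0.20, 0.25, 0.55)
    exercise_probs: tuple[float, float, float] = (0.42, 0.29, 0.29)
    smoking_probs: tuple[float, float, float] = (0.50, 0.26, 0.24)
    drinking_probs: tuple[float, float, float] = (0.10, 0.41, 0.49)
    bmi_mean: float = 28.0
    bmi_sd: float = 6.0
    income_shape: float = 2.2
    income_scale: float = 1.4
    income_cap: float = 5.0
    # latent diet factor and nutrients
    u_intercept: float = -0.55  # offsets the confounding shifts → near-even diet split
    latent_loading: float = 0.6
    nutrient_noise_sd: float = 0.8
    diet_confounding: dict[str, float] = field(default_factory=_default_confounding)
    # true outcome model
    alpha0: float = -6.0
    beta_diet: float = 0.73
    beta_age_interaction: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    # SD of PhenoAge left unexplained by age, diet and covariates; the
    # PhenoAge-acceleration spread documented for US survey adults is
    # about 5 years.
    residual_sd: float = 5.0
    psu_sd: float = 1.0
    # missingness and clamping
    missingness: dict[str, float] = field(default_factory=dict)
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.residual_sd < 0 or self.psu_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for probs in (self.education_probs, self.exercise_probs, self.smoking_probs, self.drinking_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"category probabilities must sum to 1, got {probs}")
        for fieldname, rate in self.missingness.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missingness rate for {fieldname!r} must be in [0, 1)")

    def without_confounding(self) -> "GeneratorConfig":
        """Copy with all diet–covariate confounding channels removed."""
        return replace(self, diet_confounding={})


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth emitted alongside a cohort (aligned by record id)."""

    frame: pd.DataFrame  # columns: id, u, target_phenoage, xb, diet_class


def _age_band_index(age: np.ndarray) -> np.ndarray:
    return np.select([age < 40, age < 65], [0, 1], default=2)


def generate_cohort(
    config: GeneratorConfig,
    params: dii_mod.DIIParameterTable | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw one cohort; reproducible given ``config.seed``.

    Returns the raw participant table (design fields, covariates, nutrient
    intakes, biomarkers) plus the :class:`CohortTruth` with the latent diet
    factor and the exact implanted PhenoAge targets.
    """
    if params is None:
        params = dii_mod.load_dii_parameters()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # (1) design labels and weights
    stratum_idx = rng.integers(0, config.n_strata, size=n)
    psu_idx = rng.integers(0, config.psus_per_stratum, size=n)
    weight = rng.lognormal(mean=0.0, sigma=config.weight_log_sd, size=n)

    # (2) demographics and lifestyle
    lo, hi = config.age_range
    age = lo + (hi - lo) * rng.beta(*config.age_beta, size=n)
    female = rng.random(n) < config.p_female
    race_other = rng.random(n) < config.p_race_other
    education = rng.choice(
        ["under_high_school", "high_school", "college_or_above"],
        size=n, p=config.education_probs,
    )
    exercise = rng.choice(["inactive", "moderate", "vigorous"], size=n, p=config.exercise_probs)
    smoking = rng.choice(["non", "former", "current"], size=n, p=config.smoking_probs)
    drinking = rng.choice(["non", "former", "current"], size=n, p=config.drinking_probs)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 15.0, 60.0)
    income = np.minimum(
        rng.gamma(config.income_shape, config.income_scale, size=n), config.income_cap
    )

    # (3) latent diet factor and correlated nutrient intakes
    cf = config.diet_confounding
    u = config.u_intercept + rng.normal(0.0, 1.0, size=n)
    u += cf.get("sex_female", 0.0) * female
    u += cf.get("race_other", 0.0) * race_other
    u += cf.get("age_z", 0.0) * (age - age.mean()) / max(age.std(), 1e-12)
    u += cf.get("bmi_z", 0.0) * (bmi - config.bmi_mean) / config.bmi_sd
    u += cf.get("smoking_current", 0.0) * (smoking == "current")
    u += cf.get("education_under_high_school", 0.0) * (education == "under_high_school")
    u += cf.get("education_high_school", 0.0) * (education == "high_school")
    u += cf.get("income_z", 0.0) * (income - income.mean()) / max(income.std(), 1e-12)

    eff = params.table["effect_score"].to_numpy()
    loadings = config.latent_loading * np.sign(eff)
    z = loadings * u[:, None] + rng.normal(0.0, config.nutrient_noise_sd, size=(n, len(eff)))
    mean = params.table["global_mean"].to_numpy()
    sd = params.table["global_sd"].to_numpy()
    intakes = np.maximum(mean + sd * z, 0.0)
    nut_cols = {"nut_" + name: intakes[:, j] for j, name in enumerate(params.names)}

    # (4) DII and diet class, computed forward from the emitted intakes
    nut_frame = pd.DataFrame(nut_cols)
    scored = dii_mod.score_dii_table(nut_frame, params)
    dii = scored["dii"].to_numpy()
    pro = dii >= 0.0

    # energy from macronutrients (Atwater factors), so it is consistent
    # with the intakes and correlated with the latent factor
    g = lambda name: nut_cols["nut_" + name]
    energy = 4.0 * (g("carbohydrate") + g("protein")) + 9.0 * g("total_fat") + 7.0 * g("alcohol")

    # (5) target PhenoAge with explicit, exactly known effects
    band = _age_band_index(age)
    ce = config.covariate_effects
    target = age + config.alpha0
    target += config.beta_diet * pro
    target += config.beta_age_interaction * band * pro
    target += ce.get("sex_male", 0.0) * (~female)
    target += ce.get("race_other", 0.0) * race_other
    target += ce.get("bmi", 0.0) * (bmi - config.bmi_mean)
    target += ce.get("energy", 0.0) * (energy - 2000.0)
    target += ce.get("smoking_former", 0.0) * (smoking == "former")
    target += ce.get("smoking_current", 0.0) * (smoking == "current")
    target += ce.get("drinking_former", 0.0) * (drinking == "former")
    target += ce.get("drinking_current", 0.0) * (drinking == "current")
    target += ce.get("exercise_moderate", 0.0) * (exercise == "moderate")
    target += ce.get("exercise_vigorous", 0.0) * (exercise == "vigorous")
    target += ce.get("education_high_school", 0.0) * (education == "high_school")
    target += ce.get("education_college_or_above", 0.0) * (education == "college_or_above")
    target += ce.get("income", 0.0) * (income - 2.5)

    psu_key = stratum_idx * config.psus_per_stratum + psu_idx
    psu_effects = rng.normal(0.0, config.psu_sd, size=config.n_strata * config.psus_per_stratum)
    target += psu_effects[psu_key]
    target += rng.normal(0.0, config.residual_sd, size=n)

    # (6)+(7) invert the PhenoAge chain and solve rdw to hit xb exactly
    xb_needed = np.asarray(pa.invert_phenoage(target))
    consts = pa.DEFAULT_CONSTANTS
    xb_partial = consts.intercept_xb + consts.coefs["chron_age"] * age
    for name, value in REFERENCE_BIOMARKERS.items():
        coef = consts.coefs[name]
        xb_partial += coef * (np.log(value) if name == "crp" else value)
    rdw = (xb_needed - xb_partial) / consts.coefs["rdw"]
    if config.clamp:
        bad = (rdw < RDW_PLAUSIBLE[0]) | (rdw > RDW_PLAUSIBLE[1])
        if bad.any():
            ids = np.flatnonzero(bad)[:20].tolist()
            raise ValueError(
                f"{int(bad.sum())} records need rdw outside {RDW_PLAUSIBLE} "
                f"to reach their target PhenoAge (first ids: {ids})"
            )

    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "stratum": np.char.add("S", (stratum_idx + 1).astype(str)),
            "psu": np.char.add("P", (psu_idx + 1).astype(str)),
            "weight": weight,
            "chron_age": age,
            "sex": np.where(female, "female", "male"),
            "race": np.where(race_other, "other", "non_hispanic_white"),
            "education": education,
            "income_poverty_ratio": income,
            "exercise": exercise,
            "smoking": smoking,
            "drinking": drinking,
            "bmi": bmi,
            "energy": energy,
            **{k: np.full(n, v) for k, v in REFERENCE_BIOMARKERS.items()},
            "rdw": rdw,
            **nut_cols,
        }
    )
    truth = CohortTruth(
        frame=pd.DataFrame(
            {
                "id": np.arange(n),
                "u": u,
                "target_phenoage": target,
                "xb": xb_needed,
                "diet_class": np.where(pro, "pro_inflammatory", "anti_inflammatory"),
            }
        )
    )
    return records, truth


def inject_missingness(
    records: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Independent per-field Bernoulli masking at ``config.missingness`` rates.

    Reproducible: the masking stream is derived from ``config.seed``.
    Fields absent from the rate map are untouched.
    """
    for fieldname, rate in config.missingness.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missingness rate for {fieldname!r} must be in [0, 1)")
        if fieldname not in records.columns:
            raise ValueError(f"unknown field {fieldname!r}")
    out = records.copy()
    rng = np.random.default_rng((config.seed, 0x5EED))
    for fieldname in sorted(config.missingness):
        rate = config.missingness[fieldname]
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        col = out[fieldname]
        if col.dtype.kind in "OU":
            out[fieldname] = col.where(~mask, other=None)
        else:
            out[fieldname] = col.mask(mask, other=np.nan)
    return out
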