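"""Phenotypic age (PhenoAge) scoring.

PhenoAge maps chronological age plus nine routine clinical biomarkers onto
a years scale through a Gompertz mortality model: a linear predictor ``xb``
feeds a 10-year mortality CDF ``M``, which is re-expressed as the
chronological age at which an average person carries the same mortality
risk.  Higher PhenoAge than chronological age indicates accelerated
physiological aging.

Units are a documented assumption (the published equation omits them):
albumin g/L, creatinine µmol/L, glucose mmol/L, CRP mg/dL (entered as its
natural log), lymphocyte percent 0–100, mean cell volume fL, red-cell
distribution width %, alkaline phosphatase U/L, white blood cell count
10^3 cells/µL, age in years.  Supply converted values if your table uses
other units.

The full chain is analytically invertible; :func:`invert_phenoage` returns
the ``xb`` that produces a given PhenoAge, which the synthetic cohort
generator uses to implant exactly known targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerPanel",
    "PhenoAgeConstants",
    "BIOMARKER_FIELDS",
    "compute_xb",
    "compute_mortality_score",
    "compute_phenoage",
    "phenoage_from_panel",
    "invert_phenoage",
    "score_table",
]

#: Panel fields in equation order, excluding chronological age.
BIOMARKER_FIELDS = (
    "albumin",
    "creatinine",
    "glucose",
    "crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
)


class PhenoAgeValidationError(ValueError):
    """Raised when a biomarker panel violates the model's domain."""


@dataclass(frozen=True)
class PhenoAgeConstants:
    """All constants of the published PhenoAge equations.

    ``pheno_denom`` defaults to the value as printed in the analysis this
    package operationalizes (0.09165); the original PhenoAge derivation
    uses 0.090165.  Either variant is a one-field change here.
    """

    intercept_xb: float = -19.907
    coefs: dict[str, float] = field(
        default_factory=lambda: {
            "albumin": -0.0336,
            "creatinine": 0.0095,
            "glucose": 0.1953,
            "crp": 0.0954,  # applied to ln(CRP)
            "lymphocyte_pct": -0.0120,
            "mcv": 0.0268,
            "rdw": 0.3306,
            "alp": 0.00188,
            "wbc": 0.0554,
            "chron_age": 0.0804,
        }
    )
    gompertz_scale: float = 1.51714
    gamma: float = 0.0076927
    pheno_intercept: float = 141.50
    pheno_inner: float = -0.00553
    pheno_denom: float = 0.09165


DEFAULT_CONSTANTS = PhenoAgeConstants()

#: Assay-floor applied to CRP before the log (mg/dL); configurable per call.
DEFAULT_CRP_FLOOR = 0.01


@dataclass(frozen=True)
class BiomarkerPanel:
    """One participant's inputs to the PhenoAge equations.

    CRP at or below zero is floored to ``crp_floor`` before the log,
    reflecting assay detection limits.
    """

    albumin: float
    creatinine: float
    glucose: float
    crp: float
    lymphocyte_pct: float
    mcv: float
    rdw: float
    alp: float
    wbc: float
    chron_age: float

    def validate(self, crp_floor: float = DEFAULT_CRP_FLOOR) -> None:
        for name in BIOMARKER_FIELDS + ("chron_age",):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise PhenoAgeValidationError(f"non-finite value for {name!r}: {v!r}")
        if max(self.crp, crp_floor) <= 0:
            raise PhenoAgeValidationError("CRP must be positive after flooring")
        if not 0.0 <= self.lymphocyte_pct <= 100.0:
            raise PhenoAgeValidationError(
                f"lymphocyte_pct must be in [0, 100], got {self.lymphocyte_pct}"
            )
        if self.chron_age < 0:
            raise PhenoAgeValidationError(f"chron_age must be >= 0, got {self.chron_age}")


def compute_xb(
    panel: BiomarkerPanel,
    constants: PhenoAgeConstants = DEFAULT_CONSTANTS,
    crp_floor: float = DEFAULT_CRP_FLOOR,
) -> float:
    """Linear predictor of the PhenoAge mortality model.

    The natural log is applied to CRP only; every other marker enters
    linearly.
    """
    panel.validate(crp_floor=crp_floor)
    c = constants.coefs
    xb = constants.intercept_xb
    for name in BIOMARKER_FIELDS:
        value = getattr(panel, name)
        if name == "crp":
            value = math.log(max(value, crp_floor))
        xb += c[name] * value
    xb += c["chron_age"] * panel.chron_age
    return xb


def compute_mortality_score(
    xb: float | np.ndarray, constants: PhenoAgeConstants = DEFAULT_CONSTANTS
) -> float | np.ndarray:
    """10-year mortality probability M = 1 − exp(−scale·e^xb/γ), in (0, 1).

    Guarded against overflow: very large ``xb`` returns the largest float
    below 1 rather than exactly 1, so the downstream log stays defined.
    """
    xb = np.asarray(xb, dtype=float)
    if not np.all(np.isfinite(xb)):
        raise PhenoAgeValidationError("xb must be finite")
    with np.errstate(over="ignore"):
        hazard = constants.gompertz_scale * np.exp(xb) / constants.gamma
    m = -np.expm1(-hazard)
    m = np.minimum(m, np.nextafter(1.0, 0.0))
    return float(m) if m.ndim == 0 else m


def compute_phenoage(
    m: float | np.ndarray, constants: PhenoAgeConstants = DEFAULT_CONSTANTS
) -> float | np.ndarray:
    """Phenotypic age in years from the mortality score.

    PhenoAge = intercept + ln(inner · ln(1−M)) / denom, defined for
    0 < M < 1 and strictly increasing in M.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0.0) or np.any(m >= 1.0):
        raise PhenoAgeValidationError("mortality score must lie strictly in (0, 1)")
    inner = constants.pheno_inner * np.log1p(-m)
    p = constants.pheno_intercept + np.log(inner) / constants.pheno_denom
    return float(p) if p.ndim == 0 else p


def phenoage_from_panel(
    panel: BiomarkerPanel,
    constants: PhenoAgeConstants = DEFAULT_CONSTANTS,
    crp_floor: float = DEFAULT_CRP_FLOOR,
) -> float:
    """Compose xb → M → PhenoAge for one panel.  Pure and deterministic."""
    xb = compute_xb(panel, constants, crp_floor=crp_floor)
    return float(compute_phenoage(compute_mortality_score(xb, constants), constants))


def invert_phenoage(
    target: float | np.ndarray, constants: PhenoAgeConstants = DEFAULT_CONSTANTS
) -> float | np.ndarray:
    """Exact xb that the forward chain maps to ``target`` PhenoAge years.

    Algebraically the inverse is affine:
    xb = denom·(P − intercept) + ln(γ / (−inner · scale)).
    Round-trips with the forward chain to machine precision.
    """
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise PhenoAgeValidationError("target PhenoAge must be finite")
    const = math.log(constants.gamma / (-constants.pheno_inner * constants.gompertz_scale))
    xb = constants.pheno_denom * (target - constants.pheno_intercept) + const
    # beyond the e^xb overflow ceiling no biomarker profile can reach the
    # target, so the inverse has left the forward map's achievable range
    if np.any(xb > 700.0):
        raise PhenoAgeValidationError("target PhenoAge outside the invertible range")
    return float(xb) if xb.ndim == 0 else xb


def score_table(
    table: pd.DataFrame,
    constants: PhenoAgeConstants = DEFAULT_CONSTANTS,
    crp_floor: float = DEFAULT_CRP_FLOOR,
    column: str = "phenoage",
) -> pd.DataFrame:
    """Vectorized batch scoring over a cohort table.

    Expects the canonical biomarker columns plus ``chron_age``; rows with
    any missing input get a missing PhenoAge.  Returns a copy with the
    ``phenoage`` column appended, plus ``age_accel`` (PhenoAge − age) as a
    convenience.
    """
    missing_cols = [c for c in BIOMARKER_FIELDS + ("chron_age",) if c not in table.columns]
    if missing_cols:
        raise PhenoAgeValidationError(f"table lacks biomarker columns: {missing_cols}")
    c = constants.coefs
    crp = np.maximum(table["crp"].to_numpy(dtype=float), crp_floor)
    xb = np.full(len(table), constants.intercept_xb)
    xb += c["crp"] * np.log(crp)
    for name in BIOMARKER_FIELDS + ("chron_age",):
        if name == "crp":
            continue
        xb += c[name] * table[name].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(xb)
    pheno = np.full(len(table), np.nan)
    if ok.any():
        m = compute_mortality_score(xb[ok], constants)
        pheno[ok] = compute_phenoage(m, constants)
    out = table.copy()
    out[column] = pheno
    out["age_accel"] = pheno - table["chron_age"].to_numpy(dtype=float)
    return out
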