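"""Dietary inflammatory index (DII).

The DII summarizes the inflammatory potential of a day's diet.  Each
nutrient's intake is standardized against a global reference mean and SD,
mapped to a centered percentile 2·Φ(z) − 1 in (−1, 1), multiplied by the
nutrient's literature-derived inflammatory effect score (pro-inflammatory
positive), and summed.  The score remains valid with fewer than the full
parameter set: missing nutrients simply contribute zero, and the count of
nutrients used is reported per record.

Diets are dichotomized at zero: DII < 0 anti-inflammatory, DII ≥ 0
pro-inflammatory.
"""

from __future__ import annotations

import enum
import hashlib
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DietClass",
    "DIIParameterTable",
    "DIIValidationError",
    "centered_percentile",
    "dii_score",
    "score_dii_table",
    "classify_diet",
    "load_dii_parameters",
]

N_PARAMETERS = 26


class DIIValidationError(ValueError):
    pass


class DietClass(enum.Enum):
    ANTI_INFLAMMATORY = "anti_inflammatory"
    PRO_INFLAMMATORY = "pro_inflammatory"


@dataclass(frozen=True)
class DIIParameterTable:
    """Per-nutrient global mean, SD and inflammatory effect score.

    ``version`` tags the provenance of the constants; ``checksum`` is the
    SHA-256 of the source file so runs are auditable.
    """

    table: pd.DataFrame  # columns: name, unit, global_mean, global_sd, effect_score
    version: str
    checksum: str = ""

    def __post_init__(self) -> None:
        t = self.table
        required = {"name", "unit", "global_mean", "global_sd", "effect_score"}
        if not required.issubset(t.columns):
            raise DIIValidationError(f"parameter table needs columns {sorted(required)}")
        if t["name"].duplicated().any():
            dupes = t.loc[t["name"].duplicated(), "name"].tolist()
            raise DIIValidationError(f"duplicate nutrient names: {dupes}")
        if (t["global_sd"] <= 0).any():
            bad = t.loc[t["global_sd"] <= 0, "name"].tolist()
            raise DIIValidationError(f"non-positive global SD for: {bad}")
        if not self.version:
            raise DIIValidationError("parameter table must carry a version tag")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()


def centered_percentile(z: float | np.ndarray) -> float | np.ndarray:
    """Map a standard score to 2·Φ(z) − 1 in (−1, 1).

    Odd and strictly increasing; a median intake (z = 0) contributes
    nothing to the DII.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DIIValidationError("standard score must be finite")
    out = 2.0 * stats.norm.cdf(z) - 1.0
    return float(out) if out.ndim == 0 else out


def dii_score(
    intake: dict[str, float] | pd.Series, params: DIIParameterTable
) -> tuple[float, int]:
    """DII for one record: Σ effect·(2Φ(z)−1) over non-missing nutrients.

    Returns ``(score, n_used)``.  Missing (NaN/None) nutrients are skipped;
    unknown nutrient names and negative intakes are rejected.
    """
    if isinstance(intake, pd.Series):
        intake = intake.to_dict()
    known = set(params.names)
    unknown = sorted(set(intake) - known)
    if unknown:
        raise DIIValidationError(f"unknown nutrient names: {unknown}")
    score = 0.0
    n_used = 0
    for row in params.table.itertuples(index=False):
        v = intake.get(row.name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if v < 0:
            raise DIIValidationError(f"negative intake for {row.name}: {v}")
        z = (v - row.global_mean) / row.global_sd
        score += row.effect_score * float(centered_percentile(z))
        n_used += 1
    if n_used == 0:
        raise DIIValidationError("all nutrients missing; DII undefined")
    return score, n_used


def score_dii_table(
    table: pd.DataFrame, params: DIIParameterTable, prefix: str = "nut_"
) -> pd.DataFrame:
    """Vectorized DII over a cohort table.

    Nutrient columns are ``prefix + name`` for every parameter-table name.
    Rows with every nutrient missing get missing DII and class.  Appends
    ``dii``, ``dii_n_used`` and ``diet_class`` columns.
    """
    cols = [prefix + n for n in params.names]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DIIValidationError(f"table lacks nutrient columns: {missing}")
    x = table[cols].to_numpy(dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise DIIValidationError("negative nutrient intake in table")
    mean = params.table["global_mean"].to_numpy()
    sd = params.table["global_sd"].to_numpy()
    eff = params.table["effect_score"].to_numpy()
    z = (x - mean) / sd
    contrib = eff * (2.0 * stats.norm.cdf(z) - 1.0)
    used = np.isfinite(z)
    score = np.where(used.any(axis=1), np.nansum(np.where(used, contrib, 0.0), axis=1), np.nan)
    out = table.copy()
    out["dii"] = score
    out["dii_n_used"] = used.sum(axis=1)
    out["diet_class"] = pd.array(
        [classify_diet(s).value if np.isfinite(s) else None for s in score], dtype="string"
    )
    return out


def classify_diet(dii: float) -> DietClass:
    """Dichotomize at zero; the boundary DII = 0 is pro-inflammatory."""
    if not np.isfinite(dii):
        raise DIIValidationError(f"DII must be finite, got {dii!r}")
    return DietClass.ANTI_INFLAMMATORY if dii < 0 else DietClass.PRO_INFLAMMATORY


def _default_parameter_path() -> Path:
    return Path(str(importlib.resources.files("phenodii") / "data" / "dii_parameters.csv"))


def load_dii_parameters(source: str | Path | None = None) -> DIIParameterTable:
    """Load and validate a DII parameter file (packaged default if None).

    The file is comma-delimited with columns name, unit, global_mean,
    global_sd, effect_score; ``#``-comment lines are allowed and a
    ``# version:`` comment carries the table version.  Exactly 26 rows are
    required for the packaged nutrient set.
    """
    path = Path(source) if source is not None else _default_parameter_path()
    if not path.exists():
        raise DIIValidationError(f"parameter file not found: {path}")
    raw = path.read_text()
    version = ""
    for line in raw.splitlines():
        if line.startswith("#") and "version:" in line:
            version = line.split("version:", 1)[1].strip()
    table = pd.read_csv(path, comment="#")
    if len(table) != N_PARAMETERS:
        raise DIIValidationError(
            f"expected {N_PARAMETERS} parameter rows, found {len(table)}"
        )
    checksum = hashlib.sha256(raw.encode()).hexdigest()
    return DIIParameterTable(table=table, version=version or "unversioned", checksum=checksum)
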