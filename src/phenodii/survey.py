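"""Design-based weighted linear regression for complex survey samples.

Point estimates come from weighted least squares; variances come from
Taylor linearization under the with-replacement PSU approximation, the
standard convention for stratified multi-stage surveys released with
pseudo-stratum / pseudo-PSU design variables (e.g. NHANES).  The sampling
variance of the estimating-equation total is approximated by the
between-PSU variability of the weighted score totals within each stratum,

    G = Σ_h  n_h/(n_h − 1) Σ_i (z_hi − z̄_h)(z_hi − z̄_h)ᵀ,
    z_hi = Σ_{records in PSU i of stratum h} w · e · x,

sandwiched with (XᵀWX)⁻¹.  Inference uses the t distribution with the
design degrees of freedom (#PSUs − #strata), not the normal, because
subgroup analyses can leave few PSUs.

Both β and the covariance are invariant to rescaling all weights by a
positive constant, so multi-cycle weight constructions (dividing cycle
weights by the number of cycles combined) do not change any estimate
produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
import statsmodels.api as sm

__all__ = [
    "SurveyDesign",
    "Term",
    "ModelSpec",
    "ModelFit",
    "SurveyError",
    "CollinearityError",
    "weighted_ls",
    "taylor_covariance",
    "design_df",
    "build_design_matrix",
    "fit_survey_model",
    "wald_test",
]


class SurveyError(ValueError):
    pass


class CollinearityError(SurveyError):
    pass


@dataclass(frozen=True)
class SurveyDesign:
    """Stratum / PSU / weight triple aligned with the data rows.

    ``singleton`` controls strata left with a single PSU after subsetting:
    ``"center"`` (default) scores the lone PSU against the grand mean of
    all PSU totals with a warning; ``"error"`` raises.
    """

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray
    singleton: str = "center"

    def __post_init__(self) -> None:
        s = np.asarray(self.stratum)
        p = np.asarray(self.psu)
        w = np.asarray(self.weight, dtype=float)
        if not (len(s) == len(p) == len(w)):
            raise SurveyError("stratum, psu and weight must have equal length")
        if len(w) == 0:
            raise SurveyError("empty design")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise SurveyError("sampling weights must be positive and finite")
        if self.singleton not in ("center", "error"):
            raise SurveyError("singleton must be 'center' or 'error'")
        object.__setattr__(self, "stratum", s)
        object.__setattr__(self, "psu", p)
        object.__setattr__(self, "weight", w)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        stratum: str = "stratum",
        psu: str = "psu",
        weight: str = "weight",
        singleton: str = "center",
    ) -> "SurveyDesign":
        return cls(
            stratum=frame[stratum].to_numpy(),
            psu=frame[psu].to_numpy(),
            weight=frame[weight].to_numpy(dtype=float),
            singleton=singleton,
        )

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(
            self.stratum[mask], self.psu[mask], self.weight[mask], self.singleton
        )

    def psu_labels(self) -> np.ndarray:
        """Unique PSU identifier nested in stratum."""
        return np.char.add(
            np.char.add(self.stratum.astype(str), "//"), self.psu.astype(str)
        )


@dataclass(frozen=True)
class Term:
    """One model term: a continuous column or a categorical with reference."""

    name: str
    kind: str = "continuous"  # or "categorical"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SurveyError(f"unknown term kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, ordered terms, optional product terms, confidence level."""

    outcome: str
    terms: tuple[Term, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise SurveyError("duplicate terms in model specification")
        for a, b in self.interactions:
            if a not in names or b not in names:
                raise SurveyError(f"interaction ({a}, {b}) references undeclared terms")


@dataclass(frozen=True)
class ModelFit:
    """A fitted survey-weighted linear model."""

    params: pd.Series  # β with term labels
    cov: pd.DataFrame  # linearized covariance
    df: int  # design degrees of freedom
    n: int
    sum_weights: float
    conf_level: float = 0.95
    spec: ModelSpec | None = field(default=None, compare=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        """Per-term β, SE, CI, t and p against t(design df)."""
        se = self.se
        tcrit = stats.t.ppf(0.5 + self.conf_level / 2.0, self.df)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = self.params / se
        p = 2.0 * stats.t.sf(np.abs(tval), self.df)
        return pd.DataFrame(
            {
                "term": self.params.index,
                "beta": self.params.to_numpy(),
                "se": se.to_numpy(),
                "ci_low": (self.params - tcrit * se).to_numpy(),
                "ci_high": (self.params + tcrit * se).to_numpy(),
                "t": np.asarray(tval),
                "p": p,
                "df": self.df,
            }
        ).reset_index(drop=True)

    def term_row(self, label: str) -> pd.Series:
        s = self.summary().set_index("term")
        if label not in s.index:
            raise SurveyError(f"no coefficient labelled {label!r}")
        return s.loc[label]


def weighted_ls(
    design_matrix: pd.DataFrame | np.ndarray,
    outcome: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Solve the weighted normal equations XᵀWXβ = XᵀWy.

    Invariant to a global rescaling of the weights.  Rank deficiency is a
    hard error that names the collinear columns.
    """
    X = np.asarray(design_matrix, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise SurveyError("weights must be positive")
    names = (
        list(design_matrix.columns)
        if isinstance(design_matrix, pd.DataFrame)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    sw = np.sqrt(w / w.mean())  # rescale for numerical stability; β unchanged
    Xw = X * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(Xw, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise CollinearityError(f"design matrix is rank deficient; collinear columns: {bad}")
    res = sm.WLS(y, X, weights=w).fit()
    return np.asarray(res.params)


def design_df(survey: SurveyDesign) -> int:
    """Design degrees of freedom: #distinct PSUs − #distinct strata."""
    n_psu = len(np.unique(survey.psu_labels()))
    n_strata = len(np.unique(survey.stratum.astype(str)))
    df = n_psu - n_strata
    if df < 1:
        raise SurveyError(f"design degrees of freedom must be >= 1, got {df}")
    return df


def taylor_covariance(
    design_matrix: pd.DataFrame | np.ndarray,
    outcome: np.ndarray,
    fit: np.ndarray,
    survey: SurveyDesign,
) -> np.ndarray:
    """Linearized (sandwich) covariance of β under the survey design.

    Zero when the weighted score totals are identical across PSUs within
    every stratum; invariant to a global weight rescaling.
    """
    X = np.asarray(design_matrix, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = survey.weight
    resid = y - X @ np.asarray(fit, dtype=float)
    scores = (w * resid)[:, None] * X  # per-record estimating-equation terms

    frame = pd.DataFrame(scores)
    frame["_stratum"] = survey.stratum.astype(str)
    frame["_psu"] = survey.psu_labels()
    psu_tot = frame.groupby(["_stratum", "_psu"], sort=True).sum()

    p = X.shape[1]
    G = np.zeros((p, p))
    grand_mean = psu_tot.to_numpy().mean(axis=0)
    singleton_strata = []
    for _, block in psu_tot.groupby(level="_stratum", sort=True):
        z = block.to_numpy()
        n_h = z.shape[0]
        if n_h >= 2:
            d = z - z.mean(axis=0)
            G += (n_h / (n_h - 1)) * d.T @ d
        else:
            singleton_strata.append(block.index[0][0])
            d = z[0] - grand_mean
            G += np.outer(d, d)
    if singleton_strata:
        if survey.singleton == "error":
            raise SurveyError(f"singleton-PSU strata: {singleton_strata}")
        warnings.warn(
            f"singleton-PSU strata {singleton_strata} centered at the grand mean "
            "of PSU score totals",
            stacklevel=2,
        )
    A = X.T @ (w[:, None] * X)
    Ainv = np.linalg.inv(A)
    V = Ainv @ G @ Ainv
    return (V + V.T) / 2.0


def build_design_matrix(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Intercept + dummy-coded design matrix for a :class:`ModelSpec`.

    Categorical terms are coded against their declared reference level with
    columns labelled ``name[level]``; product terms multiply the coded
    columns of their factors, labelled ``a[..]:b[..]``.
    """
    n = len(data)
    blocks: dict[str, pd.DataFrame] = {}
    X = pd.DataFrame({"(Intercept)": np.ones(n)}, index=data.index)
    for term in spec.terms:
        if term.name not in data.columns:
            raise SurveyError(f"term {term.name!r} not in data")
        col = data[term.name]
        if term.kind == "continuous":
            block = pd.DataFrame({term.name: col.to_numpy(dtype=float)}, index=data.index)
        else:
            levels = pd.unique(col.dropna().astype(str))
            ref = term.reference if term.reference is not None else sorted(levels)[0]
            if ref not in set(levels):
                raise SurveyError(
                    f"reference level {ref!r} for {term.name!r} absent from data"
                )
            others = [l for l in sorted(levels) if l != ref]
            if not others:
                raise SurveyError(f"categorical term {term.name!r} has a single level")
            block = pd.DataFrame(
                {
                    f"{term.name}[{l}]": (col.astype(str) == l).to_numpy(dtype=float)
                    for l in others
                },
                index=data.index,
            )
        blocks[term.name] = block
        X = pd.concat([X, block], axis=1)
    for a, b in spec.interactions:
        for ca in blocks[a].columns:
            for cb in blocks[b].columns:
                X[f"{ca}:{cb}"] = blocks[a][ca] * blocks[b][cb]
    return X


def fit_survey_model(
    data: pd.DataFrame, spec: ModelSpec, survey: SurveyDesign
) -> ModelFit:
    """Fit a survey-weighted linear model: WLS β, linearized covariance.

    Rows must be complete for every model variable (apply exclusions
    first).  CIs are β ± t(df, level)·SE; p-values are two-sided against
    t(design df).
    """
    if len(data) != len(survey.weight):
        raise SurveyError("data and survey design are misaligned")
    if spec.outcome not in data.columns:
        raise SurveyError(f"outcome {spec.outcome!r} not in data")
    used = [spec.outcome] + [t.name for t in spec.terms]
    if data[used].isna().any().any():
        bad = data[used].columns[data[used].isna().any()].tolist()
        raise SurveyError(f"missing values in model variables: {bad}")
    X = build_design_matrix(data, spec)
    y = data[spec.outcome].to_numpy(dtype=float)
    beta = weighted_ls(X, y, survey.weight)
    df = design_df(survey)
    V = taylor_covariance(X, y, beta, survey)
    return ModelFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(V, index=X.columns, columns=X.columns),
        df=df,
        n=len(y),
        sum_weights=float(survey.weight.sum()),
        conf_level=spec.conf_level,
        spec=spec,
    )


def wald_test(fit: ModelFit, term_subset: list[str]) -> dict[str, float]:
    """Joint Wald test that a coefficient subset is zero.

    W = βₛᵀVₛ⁻¹βₛ is referred to F = W/q against F(q, df − q + 1).  With
    q = 1 this reproduces the squared-t test for that coefficient.
    """
    if not term_subset:
        raise SurveyError("term subset must be non-empty")
    missing = [t for t in term_subset if t not in fit.params.index]
    if missing:
        raise SurveyError(f"terms not in fit: {missing}")
    b = fit.params[term_subset].to_numpy()
    V = fit.cov.loc[term_subset, term_subset].to_numpy()
    q = len(term_subset)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise SurveyError("singular covariance submatrix in Wald test") from exc
    W = float(b @ Vinv @ b)
    df2 = fit.df - q + 1
    if df2 < 1:
        raise SurveyError("not enough design degrees of freedom for the Wald test")
    F = W / q
    p = float(stats.f.sf(F, q, df2))
    return {"wald": W, "F": F, "df1": q, "df2": df2, "p": p}
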