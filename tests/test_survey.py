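"""Design-based regression engine: WLS, Taylor variance, Wald tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phenodii.survey import (
    CollinearityError,
    ModelSpec,
    SurveyDesign,
    SurveyError,
    Term,
    design_df,
    fit_survey_model,
    taylor_covariance,
    wald_test,
    weighted_ls,
)

from conftest import make_survey_frame


def jackknife_covariance(X, y, w, stratum, psu, beta):
    """Independent delete-one-PSU (JKn) oracle, coded from its definition."""
    X = np.asarray(X, dtype=float)
    labels = np.char.add(np.char.add(stratum.astype(str), "//"), psu.astype(str))
    p = X.shape[1]
    V = np.zeros((p, p))
    for h in np.unique(stratum):
        psus_h = np.unique(labels[stratum == h])
        n_h = len(psus_h)
        for lab in psus_h:
            keep = labels != lab
            wj = w.copy()
            wj[(stratum == h) & keep] *= n_h / (n_h - 1)
            Xk, yk, wk = X[keep], y[keep], wj[keep]
            bj = np.linalg.solve((Xk.T * wk) @ Xk, (Xk.T * wk) @ yk)
            d = bj - beta
            V += (n_h - 1) / n_h * np.outer(d, d)
    return V


def test_weighted_ls_perfect_fit():
    X = pd.DataFrame({"const": np.ones(3), "x": [0.0, 1.0, 2.0]})
    beta = weighted_ls(X, np.array([0.0, 1.0, 2.0]), np.ones(3))
    assert beta == pytest.approx([0.0, 1.0], abs=1e-12)


def test_weighted_ls_hand_oracle():
    # x=(0,1,2), y=(0,1,1), w=(1,1,2): normal equations give (2/11, 5/11)
    X = pd.DataFrame({"const": np.ones(3), "x": [0.0, 1.0, 2.0]})
    beta = weighted_ls(X, np.array([0.0, 1.0, 1.0]), np.array([1.0, 1.0, 2.0]))
    assert beta == pytest.approx([2 / 11, 5 / 11], abs=1e-12)


def test_equal_weights_reduce_to_ols():
    frame = make_survey_frame(80, seed=2)
    X = pd.DataFrame({"const": np.ones(len(frame)), "x": frame["x"]})
    beta = weighted_ls(X, frame["y"].to_numpy(), np.full(len(frame), 3.7))
    ols = sm.OLS(frame["y"].to_numpy(), X.to_numpy()).fit().params
    assert beta == pytest.approx(np.asarray(ols), abs=1e-10)


def test_weight_scale_invariance():
    frame = make_survey_frame(60, seed=3)
    X = pd.DataFrame({"const": np.ones(len(frame)), "x": frame["x"]})
    y, w = frame["y"].to_numpy(), frame["weight"].to_numpy()
    surv1 = SurveyDesign.from_frame(frame)
    surv7 = SurveyDesign(frame["stratum"].to_numpy(), frame["psu"].to_numpy(), 7.0 * w)
    b1 = weighted_ls(X, y, w)
    b7 = weighted_ls(X, y, 7.0 * w)
    assert b1 == pytest.approx(b7, abs=1e-10)
    V1 = taylor_covariance(X, y, b1, surv1)
    V7 = taylor_covariance(X, y, b7, surv7)
    assert V1 == pytest.approx(V7, abs=1e-10)


def test_collinearity_names_offending_column():
    X = pd.DataFrame({"const": np.ones(10), "x": np.arange(10.0), "x2": 2 * np.arange(10.0)})
    with pytest.raises(CollinearityError, match="x"):
        weighted_ls(X, np.arange(10.0), np.ones(10))


def test_design_df_arithmetic():
    surv = SurveyDesign(
        np.repeat(np.arange(15), 2), np.tile([1, 2], 15), np.ones(30)
    )
    assert design_df(surv) == 15
    small = SurveyDesign(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2]), np.ones(4))
    assert design_df(small) == 2
    degenerate = SurveyDesign(np.array([1, 2]), np.array([1, 1]), np.ones(2))
    with pytest.raises(SurveyError):
        design_df(degenerate)


def test_taylor_zero_when_psu_totals_identical():
    # mirror-image PSUs within each stratum: no between-PSU variability
    stratum = np.repeat(["A", "B"], 4)
    psu = np.tile(np.repeat(["1", "2"], 2), 2)
    x = np.tile([0.0, 1.0], 4)
    y = np.tile([0.3, 1.9], 4)
    w = np.ones(8)
    X = pd.DataFrame({"const": np.ones(8), "x": x})
    surv = SurveyDesign(stratum, psu, w)
    beta = weighted_ls(X, y, w)
    V = taylor_covariance(X, y, beta, surv)
    assert V == pytest.approx(np.zeros((2, 2)), abs=1e-12)


def test_taylor_matches_jackknife_oracle_on_toy_data():
    """Balanced 12-record, 3-stratum instance: linearization vs JKn ≤ 15%."""
    stratum = np.repeat(["A", "B", "C"], 4)
    psu = np.tile(np.repeat(["1", "2"], 2), 3)
    x = np.tile([0.0, 1.0], 6)
    y = np.array([1.0, 2.1, 1.2, 1.9, 0.9, 2.2, 1.1, 2.0, 1.0, 1.8, 1.3, 2.2])
    w = np.array([1.0, 1.2, 0.9, 1.1, 1.0, 1.0, 1.3, 0.8, 1.1, 1.0, 0.9, 1.2])
    X = pd.DataFrame({"const": np.ones(12), "x": x})
    surv = SurveyDesign(stratum, psu, w)
    beta = weighted_ls(X, y, w)
    V = taylor_covariance(X, y, beta, surv)
    Vj = jackknife_covariance(X, y, w, stratum, psu, beta)
    assert np.diag(V) == pytest.approx(np.diag(Vj), rel=0.15)


def test_degenerate_design_matches_robust_ols():
    """One stratum, one record per PSU, equal weights ≈ HC-robust OLS."""
    rng = np.random.default_rng(8)
    n = 300
    x = rng.normal(size=n)
    y = 1.0 + 0.5 * x + rng.normal(scale=1.0 + 0.5 * np.abs(x), size=n)
    X = pd.DataFrame({"const": np.ones(n), "x": x})
    surv = SurveyDesign(np.zeros(n, dtype=int), np.arange(n), np.ones(n))
    beta = weighted_ls(X, y, np.ones(n))
    ols = sm.OLS(y, X.to_numpy()).fit(cov_type="HC1")
    assert beta == pytest.approx(np.asarray(ols.params), abs=1e-10)
    se = np.sqrt(np.diag(taylor_covariance(X, y, beta, surv)))
    assert se == pytest.approx(np.asarray(ols.bse), rel=0.10)


def test_singleton_stratum_handling():
    frame = make_survey_frame(40, n_strata=3, seed=5)
    frame.loc[frame["stratum"] == "S3", "psu"] = "P1"  # S3 collapses to one PSU
    X = pd.DataFrame({"const": np.ones(len(frame)), "x": frame["x"]})
    y, w = frame["y"].to_numpy(), frame["weight"].to_numpy()
    beta = weighted_ls(X, y, w)
    surv = SurveyDesign.from_frame(frame, singleton="center")
    with pytest.warns(UserWarning, match="singleton"):
        V = taylor_covariance(X, y, beta, surv)
    assert np.all(np.diag(V) > 0)
    strict = SurveyDesign.from_frame(frame, singleton="error")
    with pytest.raises(SurveyError, match="singleton"):
        taylor_covariance(X, y, beta, strict)


def test_fit_survey_model_contract():
    frame = make_survey_frame(200, seed=7)
    spec = ModelSpec(outcome="y", terms=(Term("x"),))
    surv = SurveyDesign.from_frame(frame)
    fit = fit_survey_model(frame, spec, surv)
    summ = fit.summary().set_index("term")
    assert fit.df == design_df(surv)
    # CIs bracket the point estimates by construction
    assert (summ["ci_low"] <= summ["beta"]).all()
    assert (summ["beta"] <= summ["ci_high"]).all()
    # covariance symmetric PSD
    V = fit.cov.to_numpy()
    assert V == pytest.approx(V.T, abs=1e-14)
    assert np.all(np.linalg.eigvalsh(V) > -1e-12)


def test_fit_rejects_missing_values():
    frame = make_survey_frame(30, seed=9)
    frame.loc[0, "x"] = np.nan
    spec = ModelSpec(outcome="y", terms=(Term("x"),))
    with pytest.raises(SurveyError, match="missing"):
        fit_survey_model(frame, spec, SurveyDesign.from_frame(frame))


def test_fit_rejects_single_level_factor():
    frame = make_survey_frame(30, seed=10)
    frame["g"] = "only"
    spec = ModelSpec(outcome="y", terms=(Term("g", "categorical", "only"),))
    with pytest.raises(SurveyError, match="single level"):
        fit_survey_model(frame, spec, SurveyDesign.from_frame(frame))


def test_wald_single_term_equals_squared_t():
    frame = make_survey_frame(150, seed=12)
    spec = ModelSpec(outcome="y", terms=(Term("x"),))
    fit = fit_survey_model(frame, spec, SurveyDesign.from_frame(frame))
    res = wald_test(fit, ["x"])
    row = fit.term_row("x")
    assert res["F"] == pytest.approx(row["t"] ** 2, abs=1e-10)
    assert res["p"] == pytest.approx(row["p"], abs=1e-10)


def test_wald_zero_coefficients():
    params = pd.Series([0.0, 0.0], index=["a", "b"])
    cov = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
    from phenodii.survey import ModelFit

    fit = ModelFit(params=params, cov=cov, df=10, n=50, sum_weights=50.0)
    res = wald_test(fit, ["a", "b"])
    assert res["wald"] == 0.0
    assert res["p"] == pytest.approx(1.0)


def test_wald_singular_submatrix_errors():
    from phenodii.survey import ModelFit

    params = pd.Series([1.0, 1.0], index=["a", "b"])
    cov = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
    fit = ModelFit(params=params, cov=cov, df=10, n=50, sum_weights=50.0)
    with pytest.raises(SurveyError, match="singular|Wald"):
        wald_test(fit, ["a", "b"])
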