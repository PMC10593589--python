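"""The PhenoAge chain: linear predictor, Gompertz mortality score, years scale."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from phenodii.phenoage import (
    DEFAULT_CONSTANTS,
    BiomarkerPanel,
    PhenoAgeConstants,
    PhenoAgeValidationError,
    compute_mortality_score,
    compute_phenoage,
    compute_xb,
    invert_phenoage,
    phenoage_from_panel,
    score_table,
)

# Frozen expected values, re-derived term by term from the printed
# equations before the implementation was written.
XB_FIXTURE = -9.777467
M_FIXTURE = 0.011123
PHENO_FIXTURE = 35.7638


def test_xb_intercept_only_panel():
    # all markers zero except CRP=1 (ln 1 = 0) at age 0 leaves the intercept
    panel = BiomarkerPanel(0, 0, 0, 1.0, 0, 0, 0, 0, 0, 0)
    assert compute_xb(panel) == pytest.approx(-19.907, abs=1e-12)


def test_xb_fixture_panel(healthy_panel):
    assert compute_xb(healthy_panel) == pytest.approx(XB_FIXTURE, abs=1e-4)


def test_xb_linearity_in_rdw(healthy_panel):
    bumped = dataclasses.replace(healthy_panel, rdw=healthy_panel.rdw + 1.0)
    assert compute_xb(bumped) - compute_xb(healthy_panel) == pytest.approx(0.3306, abs=1e-10)


def test_xb_linearity_doubled_deviation(healthy_panel):
    # doubling a marker's deviation from the reference doubles its contribution
    base = compute_xb(healthy_panel)
    one = compute_xb(dataclasses.replace(healthy_panel, wbc=healthy_panel.wbc + 2.0))
    two = compute_xb(dataclasses.replace(healthy_panel, wbc=healthy_panel.wbc + 4.0))
    assert two - base == pytest.approx(2.0 * (one - base), abs=1e-10)


def test_xb_rejects_nonfinite(healthy_panel):
    bad = dataclasses.replace(healthy_panel, albumin=float("nan"))
    with pytest.raises(PhenoAgeValidationError):
        compute_xb(bad)


def test_xb_crp_floor():
    panel = BiomarkerPanel(0, 0, 0, 0.0, 0, 0, 0, 0, 0, 0)
    assert compute_xb(panel, crp_floor=0.01) == pytest.approx(
        -19.907 + 0.0954 * math.log(0.01)
    )


def test_mortality_score_collapses_to_one_minus_exp_minus_one():
    xb0 = math.log(DEFAULT_CONSTANTS.gamma / DEFAULT_CONSTANTS.gompertz_scale)
    assert compute_mortality_score(xb0) == pytest.approx(1.0 - math.exp(-1.0), abs=1e-12)


def test_mortality_score_chained_fixture(healthy_panel):
    m = compute_mortality_score(compute_xb(healthy_panel))
    assert m == pytest.approx(M_FIXTURE, abs=1e-5)


def test_mortality_score_limits_and_overflow_guard():
    assert compute_mortality_score(-700.0) == pytest.approx(0.0, abs=1e-12)
    big = compute_mortality_score(1000.0)
    assert big < 1.0  # never exactly 1, keeps the downstream log defined
    assert compute_mortality_score(-1.0) > compute_mortality_score(-2.0)  # increasing


def test_phenoage_closed_form_at_m0():
    m0 = 1.0 - math.exp(-1.0)
    expected = 141.50 + math.log(0.00553) / 0.09165  # ≈ 84.789
    assert compute_phenoage(m0) == pytest.approx(expected, abs=1e-10)
    assert compute_phenoage(m0) == pytest.approx(84.789, abs=1e-3)


def test_phenoage_chained_fixture(healthy_panel):
    assert phenoage_from_panel(healthy_panel) == pytest.approx(PHENO_FIXTURE, abs=1e-3)


@pytest.mark.parametrize("m", [0.0, 1.0, -0.1, 1.5])
def test_phenoage_domain_errors(m):
    with pytest.raises(PhenoAgeValidationError):
        compute_phenoage(m)


def test_higher_albumin_lowers_phenoage(healthy_panel):
    higher = dataclasses.replace(healthy_panel, albumin=healthy_panel.albumin + 2.0)
    assert phenoage_from_panel(higher) < phenoage_from_panel(healthy_panel)


def test_age_shift_moves_xb_linearly(healthy_panel):
    older = dataclasses.replace(healthy_panel, chron_age=healthy_panel.chron_age + 10.0)
    assert compute_xb(older) - compute_xb(healthy_panel) == pytest.approx(0.804, abs=1e-10)


def test_invert_phenoage_closed_form():
    expected = math.log(180.8318 * 0.0076927 / 1.51714)
    assert invert_phenoage(141.50) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("xb", [-12.0, -9.0, -6.0, -3.0])
def test_invert_round_trip_over_grid(xb):
    p = compute_phenoage(compute_mortality_score(xb))
    assert invert_phenoage(p) == pytest.approx(xb, abs=1e-9)


def test_forward_round_trip_in_years(healthy_panel):
    p = phenoage_from_panel(healthy_panel)
    xb = invert_phenoage(p)
    assert compute_phenoage(compute_mortality_score(xb)) == pytest.approx(p, abs=1e-9)


def test_invert_rejects_unreachable_target():
    with pytest.raises(PhenoAgeValidationError):
        invert_phenoage(1e6)


def test_monotonicity_matches_coefficient_signs(healthy_panel):
    """∂PhenoAge/∂marker carries the sign of its printed coefficient."""
    rng = np.random.default_rng(42)
    coefs = DEFAULT_CONSTANTS.coefs
    base = dataclasses.asdict(healthy_panel)
    for _ in range(100):
        panel_kwargs = {
            "albumin": rng.uniform(35, 50),
            "creatinine": rng.uniform(50, 110),
            "glucose": rng.uniform(4, 8),
            "crp": rng.uniform(0.02, 1.0),
            "lymphocyte_pct": rng.uniform(15, 45),
            "mcv": rng.uniform(80, 100),
            "rdw": rng.uniform(11, 16),
            "alp": rng.uniform(40, 120),
            "wbc": rng.uniform(4, 11),
            "chron_age": rng.uniform(20, 85),
        }
        p0 = phenoage_from_panel(BiomarkerPanel(**panel_kwargs))
        for marker, coef in coefs.items():
            bumped = dict(panel_kwargs)
            bumped[marker] += 0.5
            p1 = phenoage_from_panel(BiomarkerPanel(**bumped))
            assert np.sign(p1 - p0) == np.sign(coef), marker
    assert base  # silence unused-fixture lint


def test_alternate_denominator_constant(healthy_panel):
    # the source-literature variant is a one-field change
    variant = PhenoAgeConstants(pheno_denom=0.090165)
    p_default = phenoage_from_panel(healthy_panel)
    p_variant = phenoage_from_panel(healthy_panel, constants=variant)
    assert p_variant != pytest.approx(p_default, abs=1e-6)


def test_score_table_matches_scalar_path(healthy_panel):
    row = dataclasses.asdict(healthy_panel)
    frame = pd.DataFrame([row, {**row, "albumin": np.nan}])
    out = score_table(frame)
    assert out.loc[0, "phenoage"] == pytest.approx(phenoage_from_panel(healthy_panel), abs=1e-9)
    assert np.isnan(out.loc[1, "phenoage"])
    assert out.loc[0, "age_accel"] == pytest.approx(out.loc[0, "phenoage"] - 40.0)
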