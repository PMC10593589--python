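import numpy as np
import pandas as pd
import pytest

from phenodii.dii import DIIParameterTable, load_dii_parameters
from phenodii.phenoage import BiomarkerPanel


@pytest.fixture(scope="session")
def dii_params() -> DIIParameterTable:
    return load_dii_parameters()


@pytest.fixture()
def healthy_panel() -> BiomarkerPanel:
    """A healthy 40-year-old profile; forward chain gives PhenoAge ≈ 35.76."""
    return BiomarkerPanel(
        albumin=43.0,
        creatinine=80.0,
        glucose=5.0,
        crp=0.1,
        lymphocyte_pct=30.0,
        mcv=90.0,
        rdw=13.0,
        alp=70.0,
        wbc=6.5,
        chron_age=40.0,
    )


@pytest.fixture()
def toy_dii_table() -> DIIParameterTable:
    """Two-nutrient table with hand-checkable contributions."""
    return DIIParameterTable(
        table=pd.DataFrame(
            {
                "name": ["A", "B"],
                "unit": ["g", "mg"],
                "global_mean": [10.0, 1.0],
                "global_sd": [2.0, 1.0],
                "effect_score": [-0.5, 0.4],
            }
        ),
        version="toy",
    )


def make_survey_frame(n: int, n_strata: int = 5, seed: int = 0) -> pd.DataFrame:
    """Small stratified two-PSU-per-stratum dataset with a linear outcome."""
    rng = np.random.default_rng(seed)
    stratum = rng.integers(0, n_strata, size=n)
    psu = rng.integers(0, 2, size=n)
    x = rng.normal(size=n)
    y = 1.0 + 0.5 * x + rng.normal(scale=0.7, size=n)
    return pd.DataFrame(
        {
            "stratum": np.char.add("S", (stratum + 1).astype(str)),
            "psu": np.char.add("P", (psu + 1).astype(str)),
            "weight": rng.uniform(0.5, 2.0, size=n),
            "x": x,
            "y": y,
        }
    )
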