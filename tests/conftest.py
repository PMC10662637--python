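import numpy as np
import pandas as pd
import pytest

from savm import FixtureConfig, GroupedTable, ScenarioParams, SmokingVapingModel, generate_bundles


@pytest.fixture(scope="session")
def small_cfg():
    """Short-horizon, reduced-age synthetic configuration for fast tests."""
    return FixtureConfig(seed=11, max_age=70, end_year=2027)


@pytest.fixture(scope="session")
def small_bundles(small_cfg):
    return generate_bundles(small_cfg)


@pytest.fixture(scope="session")
def small_model(small_bundles):
    country, reference = small_bundles
    return SmokingVapingModel(country, reference)


@pytest.fixture(scope="session")
def germany_model():
    """Full Germany-like preset: 2012-2060, ages 18-99."""
    return SmokingVapingModel.from_synthetic(seed=0)


@pytest.fixture(scope="session")
def germany_results(germany_model):
    return germany_model.fit()


@pytest.fixture
def null_params():
    """NVP scenario configured to coincide exactly with the counterfactual."""
    return ScenarioParams(
        rr_nvp=0.3, switch_scale=0.0, m_smk_init=1.0, m_nvp_init=0.0,
        m_smk_cess=1.0, m_nvp_cess=1.0, nvp_intro_year=2012,
    )


def grouped(rows, columns=("age_lo", "age_hi", "gender", "value")):
    return GroupedTable(pd.DataFrame(rows, columns=list(columns)))


@pytest.fixture
def germany_prevalence_groups():
    """The published German grouped current-smoking prevalence (2012)."""
    rows = []
    for gender in ("male", "female"):
        rows += [
            (18, 29, gender, 0.347),
            (30, 44, gender, 0.345),
            (45, 64, gender, 0.304),
            (65, 99, gender, 0.120),
        ]
    return grouped(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
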