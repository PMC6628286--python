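import numpy as np
import pandas as pd
import pytest

from dietinflam import default_parameter_reference, default_teac_table
from dietinflam.io import ParameterReference, SubjectIntake, TeacTable
from dietinflam.simulate import GeneratorConfig, generate_intakes

FINAL_COVARIATES = (
    "sex", "age", "study_area", "education", "family_history",
    "smoking", "physical_activity", "bmi", "nsaid_use",
)


@pytest.fixture(scope="session")
def reference():
    return default_parameter_reference()


@pytest.fixture(scope="session")
def teac_table():
    return default_teac_table()


@pytest.fixture
def tiny_reference():
    # two-parameter reference used in hand-computed examples
    return ParameterReference.from_records(
        [("param_a", 10.0, 2.0, -0.5), ("param_b", 1.0, 1.0, 0.4)]
    )


@pytest.fixture(scope="session")
def tiny_teac():
    return TeacTable(pd.DataFrame(
        {"item_name": ["apple", "coffee"], "teac_content": [15.0, 30.0],
         "is_coffee": [False, True]}
    ))


@pytest.fixture
def subject():
    # densities: param_a -> 14, param_b -> 1 at 2000 kcal
    return SubjectIntake(
        "subj1", 2000.0, {"param_a": 28.0, "param_b": 2.0},
        item_grams={"apple": 200.0, "coffee": 100.0},
    )


@pytest.fixture(scope="session")
def big_intakes(reference, teac_table):
    """One shared 10000-subject draw under the default configuration."""
    config = GeneratorConfig(n_subjects=10000, seed=20260929)
    return config, generate_intakes(config)


def random_study(rng: np.random.Generator, n: int = 300, beta: float = 0.0,
                 interaction: float = 0.0) -> pd.DataFrame:
    """Small logistic case-control data with a continuous exposure and a
    binary modifier, used by the null-calibration simulations."""
    x = rng.normal(size=n)
    m = rng.integers(0, 2, size=n)
    eta = -0.5 + beta * x + 0.2 * m + interaction * x * m
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"case_status": y, "exposure": x, "modifier": m})
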