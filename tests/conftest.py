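import numpy as np
import pandas as pd
import pytest

from tobrapk import CohortSpec, DosingPolicy, PopulationParameters, generate_cohort


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    return PopulationParameters()


@pytest.fixture(scope="session")
def policy() -> DosingPolicy:
    return DosingPolicy()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """300 virtual patients (100 per age group), fixed seed."""
    spec = CohortSpec(n_per_group={"<2": 100, "2-12": 100, ">12": 100}, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_covariates():
    """A mature reference patient: 70 kg, eGFR exactly 127.3 mL/min."""
    from tobrapk import PatientCovariates
    return PatientCovariates(
        age=18.0, weight=70.0, height=1.70,
        serum_creatinine=41.3 * 1.70 / 127.3, creatinine_unit="mg/dL")
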