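import numpy as np
import pandas as pd
import pytest

from dynamark.simulate import (
    Censoring,
    CovariateSpec,
    SimulationDesign,
    generate_cohort,
    table1_design,
)


@pytest.fixture(scope="session")
def table1_cohort() -> pd.DataFrame:
    return generate_cohort(table1_design(n=550, seed=1))


def single_covariate_design(n=400, beta=0.7, rate=0.2, admin=8.0, seed=0, **kw):
    return SimulationDesign(
        n=n,
        covariates=(CovariateSpec("x", "continuous", mean=0.0, sd=1.0),),
        true_beta={"x": beta},
        baseline=("exponential", rate),
        censoring=Censoring(admin=admin),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def simple_cohort() -> pd.DataFrame:
    return generate_cohort(single_covariate_design(n=400, seed=11))


@pytest.fixture(scope="session")
def toy_cohort() -> pd.DataFrame:
    """Six subjects whose two-landmark super dataset has an interior MLE."""
    return pd.DataFrame(
        {
            "id": list("ABCDEF"),
            "time": [0.5, 0.9, 1.8, 2.1, 2.6, 2.9],
            "status": [1, 1, 1, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )
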