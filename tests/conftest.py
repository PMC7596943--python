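import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kmopt.synthetic import IPDCohort, generate_ipd, oracle_km, oracle_logrank

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_cohort() -> IPDCohort:
    """Five patients with hand-checkable KM curves.

    Arm 1: events at 1 and 3, censor at 2 -> S = 1, 2/3, 0.
    Arm 2: events at 1.5 and 4            -> S = 1, 1/2, 0.
    """
    data = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 1.5, 4.0],
            "event": [1, 0, 1, 1, 1],
            "arm": [1, 1, 1, 2, 2],
        }
    )
    return IPDCohort(
        data=data, n1=3, n2=2, hr=1.0,
        baseline_rate=0.1, censor_rate=0.0, admin_time=10.0, seed=0,
    )


@pytest.fixture(scope="session")
def cohort100() -> IPDCohort:
    """The reference simulated trial: 100/arm, HR 0.5, ~30% censoring."""
    return generate_ipd(n1=100, n2=100, hr=0.5, seed=5)


@pytest.fixture(scope="session")
def curves100(cohort100):
    return oracle_km(cohort100)


@pytest.fixture(scope="session")
def truth100(cohort100):
    return oracle_logrank(cohort100)


@pytest.fixture()
def simple_points_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [0.0, 6.0, 12.0],
            "s1": [1.0, 0.9, 0.7],
            "s2": [1.0, 0.8, 0.8],
        }
    )
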