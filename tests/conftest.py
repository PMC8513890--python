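import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cdclaims.claims_model import Codebook, ObservationWindow

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def codebook() -> Codebook:
    return Codebook.default()


@pytest.fixture(scope="session")
def window() -> ObservationWindow:
    return ObservationWindow("2015-01", "2019-12")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150112)


def make_claims(rows) -> pd.DataFrame:
    """Build a canonical claims frame from (pid, month, type, code, suspected)."""
    df = pd.DataFrame(
        rows, columns=["patient_id", "month", "code_type", "code", "suspected"]
    )
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    df["suspected"] = df["suspected"].astype(bool)
    return df
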