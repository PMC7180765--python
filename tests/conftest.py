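import numpy as np
import pandas as pd
import pytest

from bulksense import LogitBulkingSensor, TABLE1_STATS, WeightConfig, generate
from bulksense.types import VariableSet


@pytest.fixture(scope="session")
def cfg() -> WeightConfig:
    return WeightConfig()


@pytest.fixture(scope="session")
def sensor() -> LogitBulkingSensor:
    return LogitBulkingSensor.default()


@pytest.fixture(scope="session")
def winter_means() -> dict[str, float]:
    """Winter mean operating conditions as sensor inputs."""
    means = {k: v[1] for k, v in TABLE1_STATS["winter"].items()}
    return {k: means[k] for k in ("T", "MLSS", "DO", "mPIX", "Q", "TN", "TP", "BOD")}


@pytest.fixture(scope="session")
def plant_records() -> pd.DataFrame:
    """A mid-sized synthetic plant dataset shared across read-only tests."""
    return generate(600, rng_seed=11)


def vset(*names: str, lag: int = 1) -> VariableSet:
    return VariableSet(tuple(names), lag=lag)


@pytest.fixture(scope="session")
def toy_records() -> pd.DataFrame:
    """Records whose bulking state depends on lagged T and MLSS only.

    Balanced classes by construction, so classifier behaviour is easy to
    reason about independently of the plant generator.
    """
    rng = np.random.default_rng(7)
    n = 260
    T = 15.0 + rng.normal(size=n)
    MLSS = 4.0 + rng.normal(size=n)
    x = np.zeros(n)
    x[1:] = 2.5 * (T[:-1] - 15.0) + 2.5 * (MLSS[:-1] - 4.0)
    p_bulk = 1.0 / (1.0 + np.exp(-x))
    bulking = rng.random(n) < p_bulk
    svi = np.where(bulking, 170.0, 130.0)
    return pd.DataFrame({"T": T, "MLSS": MLSS, "SVI": svi})
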