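import numpy as np
import pandas as pd
import pytest

from hdspath.cohort import CohortConfig, make_cohort
from hdspath.pipeline import run_pipeline

#: cohort conditions for the planted-signal recovery experiments
RECOVERY_SEED = 7


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient cohort for cheap unit tests."""
    return make_cohort(CohortConfig(n_patients=30, grid_shape=(12, 12), seed=5))


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline on the planted 400-patient cohort (shared, ~1 min)."""
    return run_pipeline(seed=RECOVERY_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_survival(times, events, **extra) -> pd.DataFrame:
    df = pd.DataFrame({"time": np.asarray(times, float),
                       "event": np.asarray(events, int)})
    for k, v in extra.items():
        df[k] = v
    return df
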