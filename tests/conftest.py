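import numpy as np
import pandas as pd
import pytest

from fshthreshold import default_study_config, simulate_cohort

#: adjustment set used throughout (the generator's active covariates)
COVARIATES = ("age", "amh", "afc", "fsh_day1", "bmi", "pcos", "por")


@pytest.fixture(scope="session")
def study_cohort_small():
    """One mid-sized study-like cohort shared by read-only tests."""
    cfg = default_study_config(n_patients=800, seed=42, round_and_clip=False)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def covariates():
    return COVARIATES


def make_cycle_frame(n=10, seed=0, **overrides) -> pd.DataFrame:
    """Small hand-controllable cycle table for I/O and filter tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "cycle_index": np.ones(n),
            "fsh_day7": rng.uniform(5, 20, n).round(2),
            "oocytes": rng.integers(0, 25, n).astype(float),
            "age": rng.uniform(22, 42, n).round(1),
            "amh": rng.uniform(0.3, 12, n).round(2),
            "canceled": np.zeros(n),
            "gonadotropin_type": ["recombinant"] * n,
        }
    )
    for key, val in overrides.items():
        df[key] = val
    return df
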