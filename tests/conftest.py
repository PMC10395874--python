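import numpy as np
import pandas as pd
import pytest

from fncdr.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=1)


def simulate_clustered(seed: int, n_patients: int, episodes_per_patient: int,
                       beta: float = 1.5, sigma_patient: float = 1.0,
                       sigma_center: float = 0.0, intercept: float = -1.5,
                       x_prevalence: float = 0.3,
                       outcome: str = "bacteremia") -> pd.DataFrame:
    """Minimal clustered logistic simulation used as a fitting oracle input:
    one binary covariate with known effect, patient random intercepts, and
    optionally six centers."""
    rng = np.random.default_rng(seed)
    idx = np.repeat(np.arange(n_patients), episodes_per_patient)
    n = idx.size
    centers = rng.integers(1, 7, n_patients)
    x = rng.random(n) < x_prevalence
    v = sigma_patient * rng.standard_normal(n_patients)
    u = sigma_center * rng.standard_normal(6)
    eta = intercept + beta * x + v[idx] + u[centers[idx] - 1]
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame({
        "center_id": centers[idx],
        "patient_id": idx + 1,
        "severely_reduced_general_condition": x.astype(int),
        "randomized_fever_limit": np.where(centers[idx] % 2 == 1, 38.5, 39.0),
        outcome: y.astype(int),
    })
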