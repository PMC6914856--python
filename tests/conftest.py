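import numpy as np
import pytest

from aptw import phantom


@pytest.fixture(scope="session")
def small_spec() -> phantom.CohortSpec:
    """Desk-scale cohort: enough lesions to exercise every stage quickly."""
    return phantom.CohortSpec(
        n_patients={"MSL": 3, "WMH": 3, "HealthyWM": 2},
        lesions_per_patient=(3, 6),
        grid_shape=(48, 48, 12),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return phantom.generate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
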