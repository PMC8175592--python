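import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from covlink.simulate import CohortSpec, FieldSpec, cube_baseline, simulate_cohort_volumes

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cube_field() -> FieldSpec:
    """12^3 grid fully inside the mask (node grid 6^3 at factor 2)."""
    return FieldSpec(grid_shape=(12, 12, 12), baseline_map=cube_baseline((12, 12, 12)))


@pytest.fixture(scope="session")
def ball_field() -> FieldSpec:
    return FieldSpec()


@pytest.fixture(scope="session")
def cohort31(cube_field):
    """Default 16 + 15 cohort with volumes on the cube grid."""
    volumes, covars = simulate_cohort_volumes(CohortSpec(seed=11), cube_field, seed=12)
    return volumes, covars


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def two_group_covars(n0: int, n1: int, seed: int = 0) -> pd.DataFrame:
    """Minimal covariate table for GLM tests."""
    rng = np.random.default_rng(seed)
    n = n0 + n1
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": [0] * n0 + [1] * n1,
            "experience_years": rng.uniform(0.5, 12.0, n),
            "age": rng.uniform(24, 55, n),
            "sex": rng.integers(0, 2, n),
        }
    )
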