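import numpy as np
import pytest

from voxdose.grids import Grid
from voxdose.phantom import CohortConfig, generate_cohort, make_template


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """Desk-scale cohort configuration used across tests."""
    return CohortConfig(
        n_patients=8, n_cases=3, shape=(32, 32, 40), spacing=(6.0, 6.0, 6.0), seed=3
    )


@pytest.fixture(scope="session")
def small_template(small_cfg):
    return make_template(small_cfg)


@pytest.fixture(scope="session")
def medium_cfg() -> CohortConfig:
    """Finer grid where deformations span multiple voxels."""
    return CohortConfig(
        n_patients=8, n_cases=3, shape=(48, 48, 64), spacing=(4.0, 4.0, 3.75), seed=5
    )


@pytest.fixture(scope="session")
def medium_template(medium_cfg):
    return make_template(medium_cfg)


@pytest.fixture(scope="session")
def null_cohort(small_cfg):
    """Undeformed cohort with no planted effect (pure noise differences)."""
    cfg = CohortConfig(
        n_patients=8, n_cases=3, shape=(32, 32, 40), spacing=(6.0, 6.0, 6.0),
        deform_amplitude=0.0, effect_size=0.0, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def unit_grid():
    return Grid((8, 8, 8), (1.0, 1.0, 1.0))
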