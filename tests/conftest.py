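import numpy as np
import pytest

from longvbm.core import Volume
from longvbm.phantoms import (
    AtrophyModel,
    ClinicalCoupling,
    PhantomSpec,
    make_phantom,
    simulate_cohort,
    simulate_subject_series,
)


@pytest.fixture(scope="session")
def spec24():
    return PhantomSpec(grid_shape=(24, 24, 24), noise_sd=4.0, seed=11)


@pytest.fixture(scope="session")
def spec24_clean():
    return PhantomSpec(grid_shape=(24, 24, 24), noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def spec32_clean():
    return PhantomSpec(grid_shape=(32, 32, 32), noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def phantom32_clean(spec32_clean):
    vol, atlas = make_phantom(spec32_clean)
    return vol, atlas, spec32_clean


@pytest.fixture(scope="session")
def phantom24(spec24):
    vol, atlas = make_phantom(spec24)
    return vol, atlas, spec24


@pytest.fixture(scope="session")
def atrophy_model():
    return AtrophyModel(patient_rates={4: -0.02, 5: -0.005})


@pytest.fixture(scope="session")
def series32_clean(spec32_clean, atrophy_model):
    """Noiseless 5-visit patient series with known contraction truth."""
    series, truth = simulate_subject_series(
        spec32_clean, atrophy_model, seed=2, subject_id="pat-000"
    )
    return series, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noisy cohort for pipeline-level tests (kept cheap)."""
    spec = PhantomSpec(grid_shape=(24, 24, 24), noise_sd=4.0, seed=11)
    model = AtrophyModel(patient_rates={4: -0.02, 5: -0.005}, rate_jitter_sd=0.004)
    return simulate_cohort(
        3,
        3,
        model,
        missingness_rate=0.1,
        upgrade_year=2.5,
        clinical_coupling=ClinicalCoupling(gain=10.0, noise_sd=0.05),
        seed=5,
        spec=spec,
        visit_times=(0.0, 1.0, 3.0),
    )


def make_volume(data, voxel=2.0):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return Volume(np.asarray(data, dtype=float), aff)


@pytest.fixture
def volume_factory():
    return make_volume
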