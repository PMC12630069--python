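import numpy as np
import pytest

from protonrv import (
    NoiseModel,
    PhantomConfig,
    TreatmentPlanConfig,
    build_phantom,
    build_rp_plan,
    build_treatment_plan,
)


@pytest.fixture(scope="session")
def phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def rp_plan():
    return build_rp_plan()


@pytest.fixture(scope="session")
def small_treatment_plan():
    """Reduced treatment field (3 layers x 3 x 3 spots) for fast pipeline tests."""
    return build_treatment_plan(
        TreatmentPlanConfig(
            n_layers=3, energy_min_mev=130.0, energy_max_mev=150.0,
            ny=3, nz=3, seed=424242,
        )
    )


@pytest.fixture(scope="session")
def quiet():
    return NoiseModel.none()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
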