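import numpy as np
import pytest

from sweptmemr import (
    ClickResponseModel,
    MiddleEarParams,
    NoiseParams,
    ReflexParams,
    SweptScheduleSpec,
    simulate_binned_session,
)


@pytest.fixture(scope="session")
def me_default() -> MiddleEarParams:
    return MiddleEarParams()


@pytest.fixture(scope="session")
def rf_default() -> ReflexParams:
    return ReflexParams()


@pytest.fixture(scope="session")
def model_default(me_default) -> ClickResponseModel:
    """Shared windowed-measurement model (building it is the expensive step)."""
    return ClickResponseModel(me_default)


@pytest.fixture(scope="session")
def swept_spec() -> SweptScheduleSpec:
    return SweptScheduleSpec()


@pytest.fixture(scope="session")
def noiseless_session(swept_spec, me_default, rf_default, model_default):
    """Default swept session with noise and drift switched off."""
    nz = NoiseParams(sigma=0.0, drift_amplitude=0.0, seed=0)
    return simulate_binned_session(swept_spec, me_default, rf_default, nz, model=model_default)


@pytest.fixture(scope="session")
def noisy_session(swept_spec, me_default, rf_default, model_default):
    """Default swept session at the default noise level."""
    nz = NoiseParams(seed=2024)
    return simulate_binned_session(swept_spec, me_default, rf_default, nz, model=model_default)
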