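import numpy as np
import pytest

from pasorption import (
    AssayCalibration,
    BatchSystem,
    Condition,
    LangmuirParameters,
    RampSchedule,
)


@pytest.fixture
def bench_system() -> BatchSystem:
    """The bench-scale desorption system: 4.5 mL of 1500 mg/L PA on 10 mg CWM."""
    return BatchSystem(liquid_volume_L=0.0045, cwm_mass_mg=10.0, total_pa_mg=6.75)


@pytest.fixture
def simple_params() -> LangmuirParameters:
    return LangmuirParameters(keq=1.0, scwm=0.4)


@pytest.fixture
def unit_calibration() -> AssayCalibration:
    """A calibration with no dilution or background scaling (pure line)."""
    return AssayCalibration(slope=0.001, intercept=0.0, dilution_factor=1.0, background_scale=1.0)


@pytest.fixture
def finished_wine() -> Condition:
    return Condition.from_celsius(35.0, 15.0)


@pytest.fixture
def ramp_15pct() -> RampSchedule:
    return RampSchedule(ethanol_pct=15.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
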