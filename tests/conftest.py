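import numpy as np
import pytest

from caretactics.synthetic_population import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_population():
    """A mid-sized default-parameter population shared across tests."""
    cfg = SimulationConfig(n_initial_females=150, n_years=18, seed=11)
    bear_years, litters = simulate(cfg)
    return cfg, bear_years, litters


@pytest.fixture(scope="session")
def pressure_population():
    """A population exposed to hunting pressure ramping over the observed
    range, calibrated at low pressure so higher pressures genuinely depress
    survival (the mechanism the hunting-response module estimates)."""
    n_years = 24
    cfg = SimulationConfig(
        n_initial_females=350,
        n_years=n_years,
        seed=17,
        hunting_pressure=list(np.linspace(0.0, 0.33, n_years)),
        calibration_pressure=0.02,
        year_effect_sd=0.05,
    )
    bear_years, litters = simulate(cfg)
    return cfg, bear_years, litters
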