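import numpy as np
import pytest

from mgm import SyntheticConfig, generate_cohort
from mgm.presets import W0_CRICKET, cricket_params


@pytest.fixture(scope="session")
def cricket():
    """Default cricket-like parameter set (b_N = 1, hyperallometric defence)."""
    return cricket_params()


@pytest.fixture(scope="session")
def cricket_vb():
    """Mass-independent defence share (b_N = 0): von Bertalanffy regime."""
    return cricket_params(b_N=0.0)


@pytest.fixture(scope="session")
def W0():
    return W0_CRICKET


@pytest.fixture(scope="session")
def noiseless_cohort(cricket):
    """Deterministic cohort table (no individual variation, noise or deaths)."""
    cfg = SyntheticConfig(
        params=cricket,
        individual_cv=0.0,
        measurement_cv=0.0,
        mortality_rate=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(cricket):
    """Small stochastic cohort table for structural/IO tests."""
    cfg = SyntheticConfig(params=cricket, densities=(5, 20), seed=11)
    return generate_cohort(cfg)
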