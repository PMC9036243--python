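import numpy as np
import pytest
from hypothesis import settings

import tdlnpk as tk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def renal():
    return tk.get_study("bevacizumab_renal")


@pytest.fixture(scope="session")
def dose():
    return tk.DoseSpec(amount_mg=10.0)


@pytest.fixture(scope="session")
def week_grid():
    """0–336 h, 2-hour resolution."""
    return np.linspace(0.0, 336.0, 169)


@pytest.fixture(scope="session")
def renal_traj(renal, dose, week_grid):
    return tk.simulate(renal, dose, week_grid)
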