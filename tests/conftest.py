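import numpy as np
import pytest

from cycloclock.clock import CLOCK_INIT, ClockParams, LDSchedule, clock_model
from cycloclock.core import SimulationConfig, integrate


@pytest.fixture(scope="session")
def ld_schedule():
    return LDSchedule()


@pytest.fixture(scope="session")
def clock_free_run():
    """Long free-running clock trajectory (shared across tests)."""
    model = clock_model(ClockParams(), None)
    cfg = SimulationConfig(t_end=1400, t_transient=600, dt_out=0.1)
    return integrate(model, CLOCK_INIT, cfg)


@pytest.fixture(scope="session")
def clock_entrained(ld_schedule):
    """LD-entrained clock trajectory (shared across tests)."""
    model = clock_model(ClockParams(), ld_schedule)
    cfg = SimulationConfig(t_end=1400, t_transient=800, dt_out=0.1)
    return integrate(model, CLOCK_INIT, cfg)
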