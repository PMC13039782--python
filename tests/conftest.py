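import numpy as np
import pytest

from valveverify.calibration import MaterialSpec
from valveverify.fsi import ChannelGeometry, CouplingConfig, run_simulation
from valveverify.traces import TimeTrace, uniform_grid


def flap_geometry() -> ChannelGeometry:
    """Desk-scale channel with a leaning leaflet used across the FSI tests."""
    return ChannelGeometry(length=0.08, height=0.02, nx=32, ny=8,
                           flap_x=0.02, flap_width=0.005, flap_height=0.015,
                           flap_lean_cells=1)


def pulse_trace(T: float = 0.06, dt: float = 1e-3, peak: float = 300.0) -> TimeTrace:
    """Half-sine systolic pressure pulse over the first half of the window, Pa."""
    t = uniform_grid(T, dt)
    v = peak * np.sin(np.pi * np.minimum(t / (0.5 * T), 1.0)) * (t < 0.5 * T)
    return TimeTrace(t, v, "Pa")


def fast_coupling(dt: float = 1e-3, epsilon: float = 3e-4) -> CouplingConfig:
    return CouplingConfig(dt=dt, epsilon=epsilon, max_newton_iters=60)


@pytest.fixture(scope="session")
def flap_benchmark_run():
    """One coupled run of the flap benchmark, shared by several tests."""
    res = run_simulation(flap_geometry(), MaterialSpec(8e4, 0.4), pulse_trace(),
                         fast_coupling(), mu=0.1, dp_in_mmhg=False)
    assert res.status == "ok", res.status
    return res
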