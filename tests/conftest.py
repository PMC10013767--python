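import numpy as np
import pytest

import ioplate as ip
from ioplate import scenarios


@pytest.fixture(scope="session")
def plate():
    """Default plate: 0.5 kg, tuned to a 42 Hz natural frequency."""
    return ip.PlateConfig()


@pytest.fixture(scope="session")
def grid2_voltage(plate):
    """Simulated 120 s Grid2-like recording (20 Hz tremor riding on locomotion)."""
    params = scenarios.grid2_params(duration_s=120.0, seed=11)
    force, _, _ = ip.gen_mouse_motion(params)
    return ip.simulate_plate(plate, force)


@pytest.fixture(scope="session")
def wt_voltage(plate):
    """Matched wild-type recording (same seed, no tremor coupling)."""
    params = ip.ScenarioParams(kind="wt_mouse", duration_s=120.0, seed=11)
    force, _, _ = ip.gen_mouse_motion(params)
    return ip.simulate_plate(plate, force)


@pytest.fixture(scope="session")
def mouse_channels():
    """All three channels of one 60 s Grid2 scenario."""
    params = scenarios.grid2_params(duration_s=60.0, seed=3)
    return ip.gen_mouse_motion(params)


def sine_trace(freq_hz, duration_s=10.0, fs=1000.0, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return ip.VoltageTrace(values=amp * np.sin(2 * np.pi * freq_hz * t + phase),
                           fs_hz=fs)
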