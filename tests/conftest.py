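import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibermech import (
    FiberSpec,
    LoadingCommand,
    NoiseSpec,
    design_controller,
    run_closed_loop,
)
from fibermech.presets import GELMA_5P5PCT, GELMA_7PCT

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fiber():
    """150 um diameter fiber, 1 mm gauge length."""
    return FiberSpec.from_diameter(150.0, 1000.0)


@pytest.fixture(scope="session")
def design7():
    """Default controller designed on the 7% GelMA model."""
    return design_controller(GELMA_7PCT)


@pytest.fixture(scope="session")
def standard_command():
    return LoadingCommand(offset_uN=5.0, amplitude_uN=5.0, frequency_Hz=0.01, n_cycles=3)


@pytest.fixture(scope="session")
def trace7_noisy(design7, standard_command):
    """Closed-loop run on the 7% fiber with the study's noise level."""
    return run_closed_loop(GELMA_7PCT, design7, standard_command, NoiseSpec(), seed=1)


@pytest.fixture(scope="session")
def trace55_noisy(design7, standard_command):
    """Same controller driving the mismatched 5.5% fiber."""
    return run_closed_loop(GELMA_5P5PCT, design7, standard_command, NoiseSpec(), seed=1)


@pytest.fixture(scope="session")
def trace7_clean(design7, standard_command):
    return run_closed_loop(GELMA_7PCT, design7, standard_command, None, seed=0)


def rms_error(trace, after_s):
    mask = trace.t >= after_s
    return float(np.sqrt(np.mean((trace.F_f[mask] - trace.F_cmd[mask]) ** 2)))
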