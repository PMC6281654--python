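import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def t_grid():
    """Default delay grid: 0-7.5 ps, 10 fs step."""
    return np.arange(0.0, 7.5 + 5e-3, 1e-2)


@pytest.fixture
def t_grid_fine():
    """0-7.5 ps, 5 fs step (matches the simulation default density)."""
    return np.arange(0.0, 7.5 + 2.5e-3, 5e-3)


@pytest.fixture
def three_level_spectrum():
    """Equal-intensity sticks at 0/179/358 cm^-1: the low levels of the
    179 cm^-1 progression reached by near-origin excitation."""
    from beatmap import StickSpectrum

    return StickSpectrum.from_arrays(
        [0.0, 179.0, 358.0],
        [1.0, 1.0, 1.0],
        origin_cm1=28851.0,
        mode_labels=["origin", "179(1)", "179(2)"],
    )
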