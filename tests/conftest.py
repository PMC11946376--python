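import numpy as np
import pytest

from ssahr.signal_io import PhysioSeries
from ssahr.synthetic import SessionModel, generate_session


@pytest.fixture
def simple_series() -> PhysioSeries:
    rng = np.random.default_rng(42)
    n = 120
    hr = 70 + 3 * np.sin(2 * np.pi * np.arange(n) / 17) + rng.normal(0, 1, n)
    br = 15 + rng.normal(0, 0.3, n)
    rr = 60000.0 / hr + rng.normal(0, 30, n)
    return PhysioSeries("fixture", channels={"HR": hr, "BR": br, "RR": rr})


@pytest.fixture
def synthetic_session() -> PhysioSeries:
    return generate_session(SessionModel(duration=600, seed=11))


@pytest.fixture
def quiet_session() -> PhysioSeries:
    """Short session without outlier spikes (stable for tiny trainings)."""
    return generate_session(
        SessionModel(duration=400, outlier_rate=0.0, seed=3)
    )
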