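import numpy as np
import pytest

from hrvfc.cardiac import RRSeries
from hrvfc.simulate import SimConfig, default_partition


@pytest.fixture(scope="session")
def partition():
    return default_partition()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast end-to-end tests (structure unchanged)."""
    return SimConfig(n_controls=5, n_patients=6, seed=11)


def constant_rr(rr_ms: float = 1000.0, duration_s: float = 300.0) -> RRSeries:
    step = rr_ms / 1000.0
    n = int(duration_s / step) + 1
    return RRSeries.from_beat_times(np.arange(n) * step)
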