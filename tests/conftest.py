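import numpy as np
import pytest

from porpoisetools import GridSpec, synthetic_data as sd


@pytest.fixture(scope="session")
def small_env():
    """A modest coastal environment shared by read-only tests."""
    return sd.make_environment(GridSpec(nx=40, ny=120), seed=7)


@pytest.fixture(scope="session")
def hn_distances():
    """2000 half-normal perpendicular distances, sigma=0.12 km, W=0.3 km."""
    rng = np.random.default_rng(42)
    sigma, w = 0.12, 0.3
    out = []
    while len(out) < 2000:
        y = np.abs(rng.normal(0.0, sigma, size=4000))
        out.extend(y[y <= w].tolist())
    return np.array(out[:2000])
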