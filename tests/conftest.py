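import numpy as np
import pytest

from fatiscope.model import ModelParams, ProtocolSpec, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def slowing_trajectory(default_params):
    """30 s maximal tapping followed by a 30 s break, default parameters."""
    return simulate_trial(default_params, ProtocolSpec.tap_then_rest(30.0, 30.0))


def binned_speed_means(traj, width=10.0, t0=0.0, n_bins=3):
    """Mean trajectory speed per bin (cycles/s) — oracle-side binning."""
    out = []
    for k in range(n_bins):
        m = (traj.times >= t0 + k * width) & (traj.times < t0 + (k + 1) * width)
        out.append(float(traj.speed_t[m].mean()))
    return np.array(out)
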