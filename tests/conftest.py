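import numpy as np
import pytest

from monnet import simulate as sim


@pytest.fixture
def small_config():
    """Small, fast simulation: 4 spheroids x 4 neurons, 20 s."""
    return sim.SimulationConfig(
        n_spheroids=4, neurons_per_spheroid=4, duration=20.0,
        baseline_rate=0.2, field_size=500.0, seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_onsets(s, g1=1.7, g2=-0.712, noise_sd=1e-4, frame_rate=30.0):
    """OnsetMatrix with a fixed small noise estimate so planted onsets are
    significant under the 5-SD rule."""
    from monnet.traces import OnsetMatrix

    s = np.atleast_2d(np.asarray(s, float))
    on = OnsetMatrix(s, g1, g2, frame_rate=frame_rate)
    on.noise_sd_est = np.full(s.shape[0], noise_sd)
    return on
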