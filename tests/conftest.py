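import numpy as np
import pytest

from meaconn import SpikeTrain, build_grid


@pytest.fixture
def grid():
    return build_grid(pitch_um=300.0, boundary_row=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_poisson_train(rng, rate, duration, electrode_id="E"):
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    return SpikeTrain(electrode_id, times, 0.0, duration)


@pytest.fixture
def poisson_pair(rng):
    a = make_poisson_train(rng, 2.0, 60.0, "A")
    b = make_poisson_train(rng, 2.0, 60.0, "B")
    return a, b
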