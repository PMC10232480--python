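import numpy as np
import pytest
from hypothesis import settings

from caspi import LaserPrior, SimConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lidar_laser():
    """400 ps Gaussian pulse on a 100 ps grid."""
    return LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)


@pytest.fixture
def flim_laser():
    """Delta-like 200 ps pulse on a 50 ps grid (12.8 ns cycle)."""
    return LaserPrior("gaussian", dt=50e-12, fwhm=200e-12)


@pytest.fixture
def lidar_cfg(lidar_laser):
    return SimConfig(nt=128, dt=100e-12, n_cycle=1000, laser=lidar_laser, seed=7)


@pytest.fixture
def flim_cfg(flim_laser):
    return SimConfig(nt=256, dt=50e-12, n_cycle=50_000, laser=flim_laser, seed=7)
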