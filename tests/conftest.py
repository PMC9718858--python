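import numpy as np
import pytest

from calcohort import Ar1Model, SimulationConfig, gamma_from_decay, simulate_cohort

GAMMA_5HZ = gamma_from_decay(1.25, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model_5hz():
    """Study-parameter AR1 model with sigma = 0.1."""
    return Ar1Model(gamma=GAMMA_5HZ, noise_sigma=0.1, frame_rate_hz=5.0)


def ar1_response(spike_frames, n_frames, gamma=GAMMA_5HZ, amplitude=1.0):
    """Reference forward model: AR1 response to unit events (test oracle)."""
    c = np.zeros(n_frames)
    acc = 0.0
    drive = np.zeros(n_frames)
    np.add.at(drive, np.asarray(spike_frames, dtype=int), amplitude)
    for t in range(n_frames):
        acc = gamma * acc + drive[t]
        c[t] = acc
    return c


@pytest.fixture(scope="session")
def small_cohort():
    """Two-genotype SOM mini-cohort shared by integration tests."""
    cfg = SimulationConfig(
        cell_types=("SOM",),
        n_animals_per_group=2,
        n_fov_per_animal=1,
        n_neurons_per_fov=4,
        duration_s=100.0,
        seed=7,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth
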