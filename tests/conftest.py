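import numpy as np
import pytest

from emgsyn import build_task_design, make_ground_truth, synthesize_dataset


@pytest.fixture(scope="session")
def design():
    return build_task_design()


@pytest.fixture(scope="session")
def small_truth(design):
    # tiny planted model shared by fast tests
    return make_ground_truth(
        2, 2, T=20, M=8, seed=7, coefficient_noise_sigma=0.2,
        emg_noise_sd=0.0, design=design,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth, design):
    return synthesize_dataset(small_truth, design, reps_per_movement=2, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
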