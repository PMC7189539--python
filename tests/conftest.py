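import numpy as np
import pytest

from sitpress import classify, features, simulate
from sitpress.io import MotionClass, Side, Task
from sitpress.simulate import CompensationSpec, NoiseSpec


@pytest.fixture(scope="session")
def cfg():
    return simulate.default_config()


@pytest.fixture(scope="session")
def profile(cfg):
    return simulate.make_subject(cfg["population"], seed=123, subject_id="P1")


@pytest.fixture(scope="session")
def small_cohort(cfg):
    """2 subjects x 3 tasks x 4 classes x 2 reps = 48 trials, default noise."""
    return simulate.simulate_dataset(2, 2, config=cfg, seed=5)


@pytest.fixture(scope="session")
def tiny_grid():
    return {"C": (1.0, 32.0), "gamma": (0.25, 2.0)}


@pytest.fixture(scope="session")
def small_model(small_cohort, tiny_grid):
    """A quick window-level model good enough for streaming-logic tests."""
    trials, _ = small_cohort
    table = features.window_feature_table(trials, window_len=50, stride=50)
    return classify.train_model(table, hyper_grid=tiny_grid, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def nc_spec(side=Side.RIGHT):
    return CompensationSpec(MotionClass.NC, 0.0, side)


@pytest.fixture(scope="session")
def noise_free():
    return NoiseSpec()


def make_trial(profile, cfg, cls=MotionClass.NC, magnitude=0.0, side=Side.RIGHT,
               task=Task.BACK_AND_FORTH, duration=2.0, seed=7, noise=None):
    spec = CompensationSpec(cls, magnitude, side)
    return simulate.simulate_trial(
        profile, task, spec, noise or NoiseSpec(), duration, seed, config=cfg
    )
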