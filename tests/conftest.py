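import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oiskit import synth
from oiskit.io import IlluminationSchedule, StimulusProtocol

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

QUIET = synth.NoiseConfig(sd_frac=0.0, drift_amp_frac=0.0)


@pytest.fixture(scope="session")
def small_scene() -> synth.SceneConfig:
    """Noiseless scene on a small grid: 0.4 mm^2 disk (radius ~10 px).

    The footprint is kept much wider than the sigma=2 spatial filter so
    plateau values survive smoothing.
    """
    return synth.SceneConfig(area_mm2=0.4, noise=QUIET)


@pytest.fixture(scope="session")
def small_grid() -> tuple:
    return (64, 64)


@pytest.fixture(scope="session")
def noiseless_session(small_scene, small_grid):
    """Two-trial noiseless multispectral session on the small grid.

    The 60-s inter-train interval keeps the decay tail of one trial out of
    the next trial's baseline window (as the study's 90-s interval does).
    """
    protocol = StimulusProtocol(n_trials=2, inter_train_s=60.0)
    recording, truth = synth.make_session(small_scene, protocol=protocol,
                                          grid=small_grid, lead_in_s=6.0)
    return recording, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_channel_schedule() -> IlluminationSchedule:
    return IlluminationSchedule()
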