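import numpy as np
import pytest

from quailkin.config import FeatureConfig, PipelineConfig
from quailkin.gait import make_gait_template
from quailkin.pipeline import run_full_chain
from quailkin.simulate import simulate_trial
from quailkin.skeleton import build_default_quail_skeleton


@pytest.fixture(scope="session")
def skeleton():
    return build_default_quail_skeleton()


@pytest.fixture(scope="session")
def level_template():
    return make_gait_template("level")


@pytest.fixture(scope="session")
def level_trial(skeleton, level_template):
    """Two level strides at 500 Hz (the standard analysis trial)."""
    return simulate_trial(skeleton, level_template, fps=500.0, n_strides=2,
                          seed=0)


@pytest.fixture(scope="session")
def noiseless_chain():
    """Full simulate -> track -> reconstruct -> analyze run, noiseless."""
    cfg = PipelineConfig(seed=1, pixel_noise_sd=0.0,
                         features=FeatureConfig(noise_sd=0.0, n_distractors=0))
    return run_full_chain(cfg)


def angle_series(angles, variable, side=""):
    sel = angles[(angles.variable == variable) & (angles.side == side)]
    return sel.sort_values("frame").value_deg.to_numpy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231208)
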