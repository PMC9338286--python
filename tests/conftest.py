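import numpy as np
import pytest

from stimchoice import GroundTruth, make_design, simulate_session
from stimchoice.simulate import DesignConfig


@pytest.fixture
def base_design_config():
    return DesignConfig(q_max_a=2, q_max_b=6, rho=2.2, eta=2.5)


@pytest.fixture
def base_truth():
    return GroundTruth(rho=2.2, eta=2.5, epsilon=-0.25)


@pytest.fixture
def session_df(base_design_config, base_truth):
    design = make_design(base_design_config, seed=11)
    return simulate_session(base_truth, design, seed=42, session_id="sess01")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
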