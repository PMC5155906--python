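import numpy as np
import pytest

from hiercoop.agents import AgentParams, EmpiricalParams
from hiercoop.game_core import GameConfig, records_to_frame
from hiercoop.synthetic_data import StudyDesign, generate_study


@pytest.fixture
def config():
    return GameConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nash_params():
    return AgentParams(kind="nash")


@pytest.fixture
def noiseless_empirical():
    return AgentParams(kind="empirical").with_noise_sd(0.0)


@pytest.fixture(scope="session")
def small_study():
    """Two sessions per treatment with default empirical agents, fixed seed."""
    design = StudyDesign(
        groups_per_treatment={t: 2 for t in
                              ("control", "earned", "random", "earned_no_coop", "random_no_coop")},
        master_seed=777,
    )
    return generate_study(design)


@pytest.fixture(scope="session")
def small_study_frame(small_study):
    return records_to_frame(small_study)
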