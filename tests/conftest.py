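import pytest

from cogtutor.environments import EnvConfig, RewardSpec, TaskGraph, preset_env
from cogtutor.metalevel import solve


@pytest.fixture(scope="session")
def toy2_env():
    return preset_env("toy2")


@pytest.fixture(scope="session")
def toy2_q(toy2_env):
    return solve(toy2_env)


@pytest.fixture(scope="session")
def toy21_env():
    """Two-step chain-pair fixture: two branches of depth 2, small supports."""
    return EnvConfig(
        graph=TaskGraph.from_branching((2, 1)),
        reward_by_depth={1: RewardSpec.discrete((-1, 1)), 2: RewardSpec.discrete((-2, 2))},
        click_cost=0.25,
        name="toy21",
    )


@pytest.fixture(scope="session")
def toy212_env():
    """Reduced three-step tree with binary supports (oracle-sized)."""
    return EnvConfig(
        graph=TaskGraph.from_branching((2, 1, 2)),
        reward_by_depth={1: RewardSpec.discrete((-1, 1)),
                         2: RewardSpec.discrete((-2, 2)),
                         3: RewardSpec.discrete((-8, 8))},
        click_cost=1.0,
        name="toy212",
    )


@pytest.fixture(scope="session")
def small_env():
    """[2,1,2] tree with the full training reward structure."""
    return preset_env("training_3step_small")


@pytest.fixture(scope="session")
def small_q(small_env):
    return solve(small_env)
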