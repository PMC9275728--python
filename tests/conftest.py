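import pytest

from deepbubble import BubbleSpec, load_fixture_environments


@pytest.fixture(scope="session")
def fixture_pairs():
    """The ten shipped (Environment, GasProperties) pairs."""
    return load_fixture_environments()


@pytest.fixture(scope="session")
def pairs_by_name(fixture_pairs):
    return {(env.name, gas.gas): (env, gas) for env, gas in fixture_pairs}


@pytest.fixture(scope="session")
def make_spec(pairs_by_name):
    def _make(env_name: str, gas: str, R0: float, **kwargs) -> BubbleSpec:
        env, gasp = pairs_by_name[(env_name, gas)]
        return BubbleSpec(R0=R0, env=env, gas=gasp, **kwargs)

    return _make


ENV_NAMES = [
    "warm_surface",
    "cold_surface",
    "depth_1000m",
    "depth_2000m",
    "depth_3500m",
]
DEEP_NAMES = ["depth_1000m", "depth_2000m", "depth_3500m"]
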