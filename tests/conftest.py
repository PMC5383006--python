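import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trastecon import synthetic, trial_network
from trastecon.cea import load_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    synthetic.generate_base_case_fixtures(out)
    return out


@pytest.fixture(scope="session")
def arms(fixture_dir):
    return trial_network.load_arm_table(fixture_dir / "trial_arms.csv")


@pytest.fixture(scope="session")
def networks(arms):
    return trial_network.build_networks(arms)


@pytest.fixture(scope="session")
def cea_network(networks):
    return trial_network.select_cea_network(networks, merge_long_arms=True)


@pytest.fixture(scope="session")
def phare_network(arms):
    """Postulated 4-node cardiac network pooling all 12-month arms."""
    subset = [a for a in arms if a.trial_id in ("BCIRG006", "FinHer", "PHARE")]
    merged = trial_network.relabel_and_merge(
        subset,
        {
            "12m-con-atR-ddfs": "12m-ddfs",
            "12m-con-later-ddfs": "12m-ddfs",
            "12m-seqcon-ddfs": "12m-ddfs",
            "6m-seqcon-ddfs": "6m-ddfs",
        },
    )
    (net,) = trial_network.build_networks(merged)
    return net


@pytest.fixture(scope="session")
def base_config(fixture_dir):
    return load_config(fixture_dir / "config.yaml")


@pytest.fixture(scope="session")
def flat_life_table():
    """Zero-mortality life table for analytic Markov checks."""
    return np.zeros(101)
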