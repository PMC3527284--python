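import pytest

from simfarm.backend import BackendConfig
from simfarm.balance import LoadBalanceConfig
from simfarm.config import GlobalConfig
from simfarm.fixtures import get_model


@pytest.fixture
def birth_death():
    return get_model("birth_death")


@pytest.fixture
def decay():
    return get_model("decay")


@pytest.fixture
def isomerization():
    return get_model("isomerization")


@pytest.fixture
def dimerization():
    return get_model("dimerization")


@pytest.fixture
def fast_config(tmp_path):
    """Global configuration suitable for desk-scale runs: small balancing
    target, two local slots, work dir under tmp."""
    return GlobalConfig(
        balance=LoadBalanceConfig(t_target=0.2),
        backend=BackendConfig(max_parallel=2, seed=0),
        work_dir=tmp_path / "work",
    )
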