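import numpy as np
import pytest

from rrmm_cea import base_case, default_config
from rrmm_cea.engine import ArmResult, CohortTrace


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def model_and_base(config):
    return base_case(config)


@pytest.fixture(scope="session")
def model(model_and_base):
    return model_and_base[0]


@pytest.fixture(scope="session")
def base_result(model_and_base):
    return model_and_base[1]


def make_arm_result(name: str, cost: float, qaly: float, ly: float) -> ArmResult:
    """ArmResult with prescribed totals and a trivial one-cycle trace,
    for testing comparison arithmetic in isolation from the engine."""
    trace = CohortTrace(
        occupancy=np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        cost_by_cycle=np.array([cost]),
        qaly_by_cycle=np.array([qaly]),
        ly_by_cycle=np.array([ly]),
    )
    return ArmResult(arm=name, total_cost=cost, total_qaly=qaly, total_ly=ly, trace=trace)
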