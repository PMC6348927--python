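import numpy as np
import pytest

from acinosim.config import GeometryConfig
from acinosim.flowfield import FlowField
from acinosim.geometry import build_acinus
from acinosim.ventilation import BreathingWaveform, build_schedule


@pytest.fixture(scope="session")
def full_tree():
    return build_acinus(GeometryConfig(seed=0))


@pytest.fixture(scope="session")
def schedule_tv500(full_tree):
    return build_schedule(full_tree, BreathingWaveform(q_inlet_lpm=15.0,
                                                       inhale_s=2.0))


@pytest.fixture(scope="session")
def schedule_tv1000(full_tree):
    return build_schedule(full_tree, BreathingWaveform(q_inlet_lpm=15.0,
                                                       inhale_s=4.0))


@pytest.fixture(scope="session")
def flow_tv500(full_tree, schedule_tv500):
    return FlowField(full_tree, schedule_tv500)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
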