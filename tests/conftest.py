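import numpy as np
import pytest

from diffeffector import core_kinematics as ck
from diffeffector.effector import (geometric_arm_26, relu_point_mass_24,
                                   rigid_tendon_arm_26)


@pytest.fixture(scope="session")
def arm_params() -> ck.TwoLinkParams:
    return ck.TwoLinkParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arm26():
    return rigid_tendon_arm_26()


@pytest.fixture(scope="session")
def arm26_geometric():
    return geometric_arm_26()


@pytest.fixture(scope="session")
def point_mass():
    return relu_point_mass_24()
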