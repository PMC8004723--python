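import numpy as np
import pytest

from fdswts.policies import Policy


class FixedArmPolicy(Policy):
    """Test helper: always plays one fixed arm and ignores feedback."""

    kind = "fixed"

    def __init__(self, arm_count: int, arm: int = 0):
        super().__init__(arm_count)
        self.arm = arm

    def select(self, rng, mu_t=None):
        return self.arm

    def update(self, arm, reward):
        pass


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fixed_arm_policy():
    return FixedArmPolicy
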