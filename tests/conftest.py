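import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(values, frame_interval_s=1.0):
    from wormsleep import ActivityTrace

    return ActivityTrace(values=np.asarray(values, dtype=float),
                         frame_interval_s=frame_interval_s)


@pytest.fixture
def wake_sleep_trace():
    """Twenty wake-level values followed by five silent frames."""
    return make_trace([100.0] * 20 + [0.0] * 5)


class ScriptedWorm:
    """Deterministic test double: high noisy activity until ``sleep_at``,
    then permanent zero activity; optionally wakes to taps with fixed
    probability drawn from its own rng."""

    def __init__(self, sleep_at=200, response_prob=0.0, seed=0,
                 wake_level=100.0, wake_noise=10.0, dt=1.0):
        self.rng = np.random.default_rng(seed)
        self.sleep_at = sleep_at
        self.response_prob = response_prob
        self.wake_level = wake_level
        self.wake_noise = wake_noise
        self.dt = dt
        self.f = 0
        self.tap_frames = []
        self.awake_until = 0

    def step(self, taps_now):
        self.f += 1
        if taps_now:
            self.tap_frames.append(self.f)
            if self.f >= self.sleep_at and self.rng.random() < self.response_prob:
                self.awake_until = self.f + 10
        awake = self.f < self.sleep_at or self.f < self.awake_until
        if awake:
            return float(self.wake_level + self.rng.normal(0, self.wake_noise))
        return 0.0

    def behavior_trace(self):
        return None
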