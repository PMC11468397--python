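import numpy as np
import pytest

import circapower as cp


@pytest.fixture(scope="session")
def seven_week():
    return cp.seven_week_protocol()


@pytest.fixture(scope="session")
def dd_week():
    return cp.dd_observation_protocol(7)


@pytest.fixture(scope="session")
def control_trace(seven_week):
    """One simulated control animal over the full 7-week protocol."""
    return cp.simulate_animal(
        cp.SimParams(seed=11), seven_week, "ctl-01", group="control"
    )


def make_tone_trace(period_h=24.0, n_days=7, bin_min=6.0, mean=10.0, amp=5.0, phase=0.0):
    """Noise-free cosine activity trace, DD schedule."""
    n = int(n_days * 1440 / bin_min)
    t = np.arange(n) * bin_min / 60.0
    counts = mean + amp * np.cos(2 * np.pi * t / period_h + phase)
    return cp.ActivityTrace(
        animal_id=f"tone-{period_h:g}",
        group="tone",
        start_clock="07:00",
        sampling_interval_min=bin_min,
        counts=counts,
        schedule=cp.dd_observation_protocol(n_days).schedule,
    )


@pytest.fixture(scope="session")
def tone_trace():
    return make_tone_trace()
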