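import numpy as np
import pytest
from hypothesis import settings

import fmgait as fg

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240421)


@pytest.fixture(scope="session")
def short_trial():
    """A fast 12 s noiseless-ish trial for unit tests."""
    cfg = fg.SimConfig(trial_s=12.0, noise_sd=0.02, seed=7)
    return fg.simulate_trial(cfg, 7)


@pytest.fixture(scope="session")
def clean_cycle_events():
    """Three perfect cycles with phase durations (0.3, 0.7, 0.5, 1.1) s."""
    durs = [0.3, 0.7, 0.5, 1.1]
    times, phases, t = [], [], 0.0
    for _ in range(3):
        for p, d in zip((1, 2, 3, 4), durs):
            times.append(t)
            phases.append(p)
            t += d
    times.append(t)
    phases.append(1)
    return fg.EventList(np.array(times), np.array(phases))
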